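"""Distance models for an open-ended conceptual domain (animals).

Animals have no single agreed geometry, so several distance models compete:
embedding-vector cosine distance, semantic cluster jumps, first-principal-
component distance, and unsigned word-frequency difference. The synthetic
cohort embeds a frequency-difference effect in horizontal gaze; the example
shows that the frequency model detects it and that a partial correlation
separates correlated distance models.
"""

import numpy as np

from gazegeom import conceptspace, gazeprep, synthgaze, trialstats

geometry = synthgaze.LatentGeometry.animal_frequencies(seed=0)
freq = {w: float(geometry.coords[w][0]) for w in geometry.labels}

zs = []
for s in range(10):
    cfg = synthgaze.SessionConfig(domain="animal", n_trials=90, coupling=0.1,
                                  noise_sd=85.0, drift_sd=2.0, seed=200 + s)
    sess = synthgaze.generate_session(cfg, geometry)
    trials = gazeprep.window_median_gaze(sess.recording, sess.events)
    disp = gazeprep.displacement_series(trials)
    change = conceptspace.animal_distance_series(
        trials["word"].tolist(), "frequency", {"frequency": freq})
    res = trialstats.condition_correlation(disp, change, axis="x_signed",
                                           mode="combined")
    zs.append(res.z)

group = trialstats.group_t(zs)
print(f"frequency-distance model: mean z = {group.mean_z:.3f}, "
      f"t({group.df}) = {group.t:.2f}, p = {group.p:.2g}, "
      f"BF10 = {group.bf10:.3g}")

# toy embedding vectors whose PC1 tracks log frequency: the two models are
# correlated, and partialling out frequency removes the PC1 effect
rng = np.random.default_rng(3)
vectors = {w: np.r_[np.log10(freq[w]), rng.normal(size=4) * 0.3]
           for w in geometry.labels}
seq = [geometry.labels[i] for i in rng.integers(0, 12, size=200)]
d_pc1 = conceptspace.animal_distance_series(seq, "pc1",
                                            {"vectors": vectors}).values
d_freq = conceptspace.animal_distance_series(seq, "frequency",
                                             {"frequency": freq}).values
rho = trialstats.spearman_rho(d_pc1, d_freq)
gaze_proxy = d_freq + rng.normal(0, d_freq.std(), size=len(d_freq))
rp, p = trialstats.partial_spearman(gaze_proxy, d_pc1, d_freq)
print(f"PC1 vs frequency distances: rho = {rho:.2f}")
print(f"gaze ~ PC1 after controlling frequency: partial rho = {rp:.2f}, "
      f"p = {p:.2g}")
print("-> the PC1 effect disappears once frequency distance is partialled")
print("   out: gaze follows similarity in frequency space.")
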