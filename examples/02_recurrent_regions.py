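"""Score recurrent copy-number aberrations across samples (GISTIC-style).

Builds a 12-sample cohort whose arrays share one recurrent gained region on
top of private random aberrations, computes per-marker G-scores (summed
aberration amplitude over aberrant samples), and attaches cyclic-shift
resampling p-values, BH q-values, and significant regions.
"""

import numpy as np

from cgsig import MarkerProfile, call_cnv, cbs_segment, gistic_significance, gscore, merge_levels

rng = np.random.default_rng(5)
n_markers, n_samples = 200, 12
positions = np.arange(n_markers) * 30_000 + 30_000
profiles, segmented, calls = [], [], []
for s in range(n_samples):
    x = rng.normal(0, 0.1, n_markers)
    lo = rng.integers(0, n_markers - 20)  # one private aberration per sample
    x[lo : lo + 20] += rng.choice([-0.3, 0.3])
    if s < 9:  # recurrent gain at markers 140-159 in 9 of 12 samples
        x[140:160] += 0.35
    prof = MarkerProfile(sample_id=f"S{s:02d}", chromosomes=np.array(["8"] * n_markers, dtype=object),
                         positions=positions, log_ratios=x)
    seg = merge_levels(cbs_segment(prof, n_perm=200, seed=5), prof)
    profiles.append(prof)
    segmented.append(seg)
    calls.append(call_cnv(seg, prof))

for kind in ("gain", "loss"):
    track = gscore(profiles, segmented, calls, kind=kind)
    out = gistic_significance(track, profiles, segmented, calls,
                              n_resamples=2000, fdr=0.05, seed=5)
    n_sig = int(out.markers["significant"].sum())
    print(f"{kind}: max G = {track.g.max():.2f}, "
          f"{n_sig}/{n_markers} markers significant at FDR 0.05, "
          f"{len(out.regions)} region(s)")
    for r in out.regions.itertuples():
        print(f"  region {r.region_id}: chr{r.chromosome}:{r.start}-{r.end} "
              f"peak at {r.peak_position} (G = {r.peak_g:.2f})")
# The planted recurrent gain (markers 140-159) should surface as the one
# significant gain region; private aberrations stay within the null.
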