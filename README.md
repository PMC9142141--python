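# glomcode

Glomerular odor-coding analysis for insect olfaction studies: a tested,
reusable reimplementation of the analysis stack behind plant-headspace
coding experiments in the hawkmoth antennal lobe — calcium-imaging movie
processing and response extraction, statistical calling of
headspace-activated glomeruli, GC-EAD active-peak analysis with Kovats
retention indices, and the Bray–Curtis / ANOSIM / NMDS multivariate layer.

**Who it is for.** Researchers analyzing odor-evoked glomerular activity
(ΔF/F movies plus ROI maps), GC-EAD peak tables from multiple antennae, or
sample × feature abundance tables — and anyone who wants a seeded,
ground-truthed synthetic testbed for such pipelines.

## The core methods

*Imaging.* A 40-frame trial at 4 Hz (odor on frames 9–16) passes through
four steps: ΔF/F against the mean of pre-stimulus frames 3–7; subtraction
of a fitted photobleaching curve a + b·e^(−t/τ) (fit frames 3–7 and 26–40);
a 7-px spatial median filter; and movement correction by the integer
translation aligning frame 20 of each trial to frame 20 of the reference
trial (normalized cross-correlation, ±10 px). The response of a glomerulus
is read from a 60 µm × 60 µm ROI: 3-frame-smoothed ROI-mean trace, its
post-onset maximum averaged with the two neighboring smoothed values.

*Activation calling.* Per group and glomerulus, animals are blocks and the
18 headspaces plus the averaged dichloromethane control are 19 Friedman
treatments; Dunn's vs-control test with Bonferroni adjustment over the 18
comparisons assigns tiers p < 0.01 and p < 0.001. Responses are min–max
normalized to 0–100 per animal × glomerulus.

*GC-EAD.* Kovats retention index RI = 100(n + (rt − rt_n)/(rt_{n+1} − rt_n))
against an n-alkane ladder; single-linkage alignment of peaks across
antennae (±5 RI); a fraction is EAD-active iff ≥ 3 antennae responded at
matching retention and the fraction is present in another replicate of the
same headspace type.

*Multivariate.* Bray–Curtis d = Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ); one-way and two-way
crossed ANOSIM R = (r̄_between − r̄_within)/(M/2) with permutation p
(exhaustive on small designs); non-metric MDS minimizing Kruskal stress-1,
best of 50 restarts plus a classical-scaling warm start.

Every stage is generated, processed and scored against planted ground truth
by the synthetic-data module; see `docs/methods.md` for models, defaults
and limitations.

## Worked example

Simulate one imaging trial with three glomeruli (true peak ΔF/F 0.06, 0.00
and 0.02), run the processing chain, and extract responses:

```python
import numpy as np
from glomcode import synthetic, imaging

amps = np.array([[0.06, 0.0, 0.02]])
truth = synthetic.MovieGroundTruth(
    baseline_map=synthetic.make_baseline_map((130, 172), seed=4),
    spot_centers=synthetic.grid_spot_centers((130, 172), 3, margin=20),
    amplitudes=amps, shifts=np.zeros((1, 2), dtype=int),
    spot_sigma=5.0, seed=4,
)
movie = synthetic.generate_movie(truth, 0)
dff = imaging.background_correct(movie)
dff = imaging.median_filter_frames(dff)
for j, center in enumerate(truth.spot_centers):
    r = imaging.extract_response(dff, imaging.RoiSpec(center=center),
                                 bleach_fit_frames=imaging.DEFAULT_FIT_FRAMES)
    print(f"glomerulus {j}: true peak {amps[0, j]:.3f}  extracted {r:.4f}")
```

```
glomerulus 0: true peak 0.060  extracted 0.0377
glomerulus 1: true peak 0.000  extracted 0.0004
glomerulus 2: true peak 0.020  extracted 0.0126
```

The silent glomerulus sits at the noise floor; the responders come back in
the right order at ~0.63 of the injected peak — the deterministic
attenuation of a sharp transient by the 3-frame smoother and median filter,
identical for all glomeruli and therefore irrelevant to every downstream
rank-based statistic.

Group-structured abundance tables feed the multivariate layer the same way:

```python
from glomcode import synthetic, multivariate

spec = synthetic.GroupTableSpec(n_groups=2, n_per_group=8, n_features=20,
                                separation=1.5, seed=7)
table, labels = synthetic.generate_group_table(spec)
dist = multivariate.bray_curtis(table)
res = multivariate.anosim_oneway(dist, labels["group"].to_numpy(),
                                 n_perm=9999, seed=7)
print(f"one-way ANOSIM: R = {res.R:.3f}, p = {res.pvalue:.4f} ({res.method})")
ord_res = multivariate.nmds(dist, restarts=20, seed=7)
print(f"NMDS 2D stress: {ord_res.stress:.3f}")
```

```
one-way ANOSIM: R = 0.623, p = 0.0002 (sampled)
NMDS 2D stress: 0.145
```

R near 0.6 with p ≪ 0.01 says the two groups' volatile profiles are well
separated but overlapping at this effect size; a 2-D stress of 0.145 means
the ordination is a usable but imperfect summary of the rank structure.

A thin CLI wraps the same functions:
`glomcode simulate | imaging | activate | ead-call | anosim | ordinate |
benchmark | report` (see `glomcode --help`).

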