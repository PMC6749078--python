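# metastate

Node-centrality-based metastate detection for dynamic functional brain
networks, with test-retest reliability analysis and structural rich-club
comparison.

Resting-state fMRI functional connectivity is not static: sliding-window
correlation networks drift through a small set of recurring whole-brain
configurations ("metastates"). Most metastate pipelines cluster the raw
connectivity vectors; this package instead clusters **node centrality
patterns** — for each window, the eigenvector centrality of the
density-thresholded, Fisher-z weighted network — so a metastate is a
recurring *hub configuration* rather than a recurring edge pattern. The
package is for researchers who already have region-level BOLD time series
(e.g. AAL-90 extractions) and want state sequences, dwell/transition
dynamics, their between-session reliability, and hub/rich-club summaries.

## Method

For each subject and session:

1. **Windowed networks** — Pearson correlation of the ROI time series in a
   rectangular sliding window (default 60 s = 24 volumes at TR 2.5 s, step
   1 TR), Fisher z-transformed (`z = atanh r`). Volumes with framewise
   displacement above 0.3 mm are deleted first; subjects left with fewer
   than 200 volumes are excluded. Each window is proportionally
   thresholded to keep the strongest 40% of edges with their weights.
2. **Centrality sequence** — per-window weighted degree
   `C_D(i) = Σ_j A_ij` and eigenvector centrality
   `C_E = (1/λ₁) A C_E` (leading eigenvector of the nonnegative
   adjacency), each window's vector z-normalized to N(0, 1).
3. **Two-stage k-means++** — group-level k-means++ with correlation
   distance `d(u, v) = 1 − Pearson(u, v)` over all pooled windows, k
   chosen by the elbow of the best-inertia curve over k = 2..10; then
   per-subject Lloyd refinement initialized at the group centers. A
   metastate's pattern is the mean centrality vector of its windows.
4. **Dynamics and reliability** — per-subject dwell time (windows in a
   state, or × TR in seconds) and transition counts; across two sessions
   the intra-class correlation
   `ICC = Σ (x₁ᵢ − x̄)(x₂ᵢ − x̄) / ((n − 1) s_x²)` with the mean and
   variance pooled over all 2n observations (0.4 / 0.75 poor / good
   cutoffs), assembled into a K × K matrix (diagonal: dwell;
   off-diagonal: transitions).
5. **Hubs and rich club** — hubs are regions above mean + 1 SD of a
   state's pattern; structural networks get the weighted rich-club
   coefficient `Φw(r) = W_{>r} / Σ_{l≤E_{>r}} w_l^rank` normalized by
   1000 degree-preserving Maslov–Sneppen nulls, with `Φ_norm(r) > 1`
   signalling a rich-club effect.

A synthetic-data module plants every ground truth the pipeline estimates
(state sequences with controllable retest reliability, hub templates,
BOLD-like forward-model time series, core–periphery structural networks),
so each stage is testable end to end.

## Worked example

Recover planted metastates from synthetic centrality data and measure
their test-retest reliability (23 subjects scanned twice, 3 states over
30 regions, 227 windows/session, retest ρ = 0.8):

```python
import numpy as np
from metastate import (
    SyntheticSpec, generate_centrality_dataset, two_stage_fit, match_states,
    state_templates, state_dynamics, icc_matrix, detect_hubs,
)

spec = SyntheticSpec(n_subjects=23, n_states=3, n_regions=30,
                     windows_per_session=227, snr=5.0, retest_rho=0.8, seed=7)
labels, series = generate_centrality_dataset(spec)

fit = two_stage_fit([s[0] for s in series], k=3, seed=7)
m = match_states(fit.group_model.centers, state_templates(spec))
acc = np.mean([(m.permutation[sl] == tl[0]).mean()
               for sl, tl in zip(fit.subject_labels, labels)])
print(f"planted-state label accuracy: {acc:.3f}")

fit2 = two_stage_fit([s[1] for s in series], k=3, seed=8)
m2 = match_states(fit2.group_model.centers, fit.group_model.centers)
dyn1 = [state_dynamics(l, spec.tr_s, 3) for l in fit.subject_labels]
dyn2 = [state_dynamics(m2.permutation[l], spec.tr_s, 3)
        for l in fit2.subject_labels]
icc = icc_matrix(dyn1, dyn2)
print("dwell-time ICC (diagonal):", np.round(np.diag(icc), 2))

hubs = detect_hubs(fit.group_model.centers[0], spec.region_labels)
print(f"state-1 hubs ({len(hubs)}):", hubs.members)
```

Output:

```
planted-state label accuracy: 1.000
dwell-time ICC (diagonal): [0.54 0.67 0.84]
state-1 hubs (7): ['R001', 'R002', 'R003', 'R004', 'R005', 'R006', 'R007']
```

Every window is assigned to its planted state; dwell-time reliabilities
sit above the 0.4 poor-reliability cutoff, as expected at planted ρ = 0.8
with 23 subjects; and the detected hub set is exactly the planted one.

The same stages run from the shell: `metastate simulate` writes a
synthetic dataset, `metastate run data/ out/ --k 5 --seed 17` executes the
whole pipeline, and `construct` / `centrality` / `cluster` / `dynamics` /
`icc` / `hubs` / `richclub` expose the individual steps. Outputs are
labeled TSV tables and JSON models.

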