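# h2sync

Thalamo-cortical synchrony analysis for intracranial EEG (SEEG) seizure
recordings.

In mesial temporal lobe epilepsy, seizures end on their own, and one
candidate mechanism is a build-up of hypersynchronization between the
thalamus and temporal cortex in the last seconds of the discharge. This
package implements the full analysis chain used to quantify that idea
from depth-electrode recordings: nonlinear pairwise connectivity with
directionality, sliding-window graph degree measures, peak-centred
synchronization indices for the seizure-onset and end-of-seizure periods,
and the nonparametric group statistics that relate those indices to
seizure duration and to the spike-and-wave termination pattern. It is
aimed at epilepsy researchers working with SEEG and at anyone who needs a
tested, reproducible implementation of the h² connectivity estimator.

## The method

**Nonlinear correlation h².** For two signals X and Y in a 2 s window, the
scatterplot of Y against X is summarized by a piecewise-linear regression
curve g (equal-width amplitude bins of X, anchors at the per-bin means),
and

    h²(X→Y) = 1 − var(Y − g(X)) / var(Y),  clamped to [0, 1].

h² is asymmetric, invariant to affine rescaling of either signal, and
captures nonlinear dependence that the Pearson correlation misses. A
delay scan shifts Y by 0…26 samples (0.1 s at 256 Hz) in each direction;
the larger of the two directed maxima is the pair's connectivity weight
and the sign of its delay defines the direction of the link.

**Graphs and degrees.** Windows of 2 s slide in 1 s steps across each
15 s period of interest — seizure onset (SO: 5 s before to 10 s after the
tonic discharge) and end of seizure (ES: the last 15 s of the discharge) —
over up to seven regions: amygdala (A), hippocampus (Hip), entorhinal
cortex (EC), superior/middle/inferior temporal gyri (STG, MTG, ITG) and
thalamus (Th). Per window, a directed edge with h² > 0.4 adds one to its
source's out-degree and its target's in-degree; the thalamic (Th OUT /
Th IN) and mesio-temporal (MT OUT / MT IN) measures average these counts
over the ES windows.

**Synchronization indices.** Four per-window measures average h² over
fixed pair sets: global (all pairs), thalamic (pairs containing Th),
mesio-temporal (mesial × non-mesial pairs) and thalamo-mesial (Th ×
mesial). A period's index averages its measure across a 3 s span centred
on the measure's peak within the period.

**Group statistics.** Wilcoxon signed-rank for ES vs SO, Spearman rank
correlation and OLS R² against seizure duration, Mann–Whitney U for the
spike-and-wave pattern (A) vs other terminations (B); all two-sided.

Because raw patient recordings are not distributable, the package ships
(i) the published per-seizure index table as a packaged fixture for the
group statistics, and (ii) a synthetic SEEG generator with known
ground-truth coupling (strength, delay, direction, stability) so every
pipeline stage is testable end to end.

## Worked example

```python
>>> from h2sync import load_index_table, group_stats_report
>>> report = group_stats_report(load_index_table())
>>> print(report.summary())
Group statistics over 22 seizures (pattern A: 6, B: 16); 17 tests, no multiplicity correction.

End-of-seizure vs seizure-onset indices (Wilcoxon signed-rank):
  global index: W=0, p=4.8e-07
      th index: W=0, p=4.8e-07
      mt index: W=5, p=4.8e-06
    thmt index: W=5, p=4.8e-06
ES index vs seizure duration (Spearman):
  global index: rho=-0.441, p=0.040
      th index: rho=-0.424, p=0.049
      mt index: rho=-0.235, p=0.292
    thmt index: rho=-0.033, p=0.885
ES th index vs duration (OLS): R2=0.40, slope=-0.00047, p=0.001
Pattern A vs B (Mann-Whitney):
  global: U=95.5, p=0.0004
      th: U=96, p=0.0004
      mt: U=91, p=0.0015
    thmt: U=85, p=0.0063
  th_out: U=84, p=0.0079
  ...
```

Every synchronization index rises sharply from seizure onset to seizure
end (p < 1e-4); higher end-of-seizure synchronization goes with shorter
seizures (negative rho, R² = 0.40 for the thalamic index); and
spike-and-wave terminations show higher indices and more thalamic output
than other terminations.

The same pipeline runs end to end on synthetic data:

```python
>>> from h2sync import generate_seizure, pattern_a_scenario, analyze_seizure
>>> rec, ann, truth = generate_seizure(pattern_a_scenario(seed=42))
>>> r = analyze_seizure(rec, ann)
>>> round(r.es_indices["th"], 2), round(r.so_indices["th"], 2)
(0.96, 0.09)
>>> r.degrees["th_out"], r.degrees["th_in"]
(6.0, 0.0)
```

The thalamus-led termination injected by the generator is recovered: the
ES thalamic index far exceeds the SO index and the thalamus is a pure
sender (out-degree 6 of a possible 6).

## Analysis scripts

Numbered drivers under `analysis/` re-run the study's analyses and write
tables to `results/`: `01_published_table_stats.py` (group statistics over the
packaged table), `02_simulate_cohort.py` (a 22-seizure synthetic cohort),
`03_connectivity_pipeline.py` (full pipeline on a small cohort plus a
time-course figure), `04_estimator_recovery.py` (estimator recovery
curves). A `h2sync` command-line tool exposes the same steps
(`h2sync connect|stats|simulate|h2 --help`).

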