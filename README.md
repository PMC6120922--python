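# covattn

Analyses comparing the causal contributions of two oculomotor structures —
the frontal eye field (FEF) and the superior colliculus (SC) — to covert
spatial attention, using the saccade deficits produced by reversible
(muscimol) inactivation as a common benchmark for inactivation strength.

## The problem and the approach

Focal inactivation of either FEF or SC impairs covert detection of a
motion-direction change in the affected hemifield. But the two structures
differ in size and organisation, so the raw behavioural effects are not
directly comparable. The trick is that the same inactivations also slow
visually guided saccades into a confined region of the visual field (a
behavioural "scotoma"), giving an independent, within-session measure of
how strongly the retinotopic map was suppressed. Each session is condensed
to two statistics:

* **saccade latency asymmetry** (ms): mean saccade latency into the
  affected motion patch minus the latency into the mirror-symmetric
  unaffected patch,
  `latency_in − latency_out`;
* **Δ detection-rate asymmetry** (percentage points): the change, from the
  pre-injection to the injection epoch, in the out-minus-in hit-rate
  difference of the change-detection task,
  `100·[(out_during − in_during) − (out_before − in_before)]`.

Coupling between the two is estimated by orthogonal (total-least-squares)
regression of the detection statistic on the saccade statistic — both
variables are noisy session estimates — with the line constrained through
the origin (no saccade deficit ⇒ no predicted attention deficit, which is
where sham sessions cluster). Slope uncertainty comes from a leave-one-out
jackknife, slope differences from a rank test on bootstrap-resampled slope
distributions, and a dose–response view from a Bayesian logistic regression
(Laplace posterior, Monte-Carlo predictive band) of each session's binary
"significant deficit" outcome on its saccade asymmetry.

The package bundles the per-session summary tables of the study it models
(46 SC and 23 FEF inactivations), a synthetic-session generator with known
ground truth (psychometric trial model, scotoma'd saccade fields, and a
deterministic saccade→attention coupling), and every analysis stage as a
tested library.

## Layout

    src/covattn/        library: io, datatypes, simulate, psychometrics,
                        asymmetry (incl. scotoma mapping), regression,
                        doseresponse, pipeline, cli
    analysis/           numbered narrative drivers writing to results/
    tests/              pytest suite (unit, property, acceptance)
    scripts/acceptance.py   headline-number recomputation (JSON out)
    docs/methods.md     model and methods notes

## Worked example

```python
>>> from covattn import load_fixture, orthogonal_regression, session_points
>>> reg = orthogonal_regression(session_points(load_fixture("SC")))
>>> round(reg.slope, 3), round(reg.slope_se_jackknife, 3), reg.dof
(0.323, 0.024, 45)
>>> reg_f = orthogonal_regression(session_points(load_fixture("FEF")))
>>> round(reg_f.slope, 3), round(reg_f.slope_se_jackknife, 3), reg_f.dof
(0.083, 0.024, 22)
```

Per millisecond of inactivation-induced saccade slowing, SC inactivation
shifts detection performance by ~0.32 percentage points — about four times
the FEF coupling (~0.08). The analysis drivers narrate the rest:

    $ python analysis/01_table_regressions.py
    SC: slope 0.323 ± 0.024 (d.o.f. 45), Pearson r² 0.39
    FEF: slope 0.083 ± 0.024 (d.o.f. 22), Pearson r² 0.40
    slope difference (rank test on bootstrap slopes): p = 0
    significant 30-ms bins (SC vs FEF detection change): [(30.0, 60.0), (60.0, 90.0), (90.0, 120.0)]

    $ python analysis/02_subsample_control.py
    SC slope significantly steeper in 1000/1000 iterations
    slope ratio (SC/FEF): 3.97 ± 0.31

    $ python analysis/03_synthetic_recovery.py
    SC    coupling 0.31 -> slope 0.312 ± 0.016, 23/46 deficits, midpoint 80 ms
    FEF   coupling 0.08 -> slope 0.116 ± 0.019, 1/23 deficits, midpoint 133 ms
    SHAM  coupling 0.00 -> slope -1.947 ± 1.393, 0/30 deficits, midpoint undefined

The subsampling control shows the slope difference is not a sample-size
artefact; the synthetic run shows the pipeline recovers a known coupling
and that a deficit becomes more likely than not at a far smaller saccade
deficit for SC-like (~50–80 ms) than FEF-like (>100 ms) inactivations.

A `covattn` CLI wraps the same stages (`covattn --help`).

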