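"""Simulate a cohort with a known curve, then recover it by model search.

Generates a 20,000-subject cohort whose true hazard uses a sigmoidal log
transform located at the exposure median, runs the percentile-grid search
(16 initial Cox fits, then a local walk in mu), and prints the models with
non-trivial likelihood weight.
"""

from crshape import ModelEnsemble, SimulationDesign, default_true_curve, generate_cohort, search

true_curve = default_true_curve()  # f = log, mu at P50 (12.4 ug/m3), beta = 0.25
design = SimulationDesign(true_curve=true_curve, seed=11)
cohort = generate_cohort(design)
print(f"cohort: n={cohort.n}, events={cohort.n_events}, "
      f"exposure {cohort.exposures().min():.1f}-{cohort.exposures().max():.1f} ug/m3")

result = search(cohort)
best = result.best
print(f"\n{len(result.fitted)} models fit; best: f={best.f_kind}, tau={best.tau}, "
      f"mu={best.mu:.2f} ({best.percentile:g}th percentile), "
      f"beta={best.model.beta_hat:.4f} (se {best.model.se_beta:.4f})")

from crshape import fit_transformed_cox

truth_fit = fit_transformed_cox(cohort, true_curve.transform)
print(f"refit of the true transform: beta={truth_fit.beta_hat:.4f} "
      f"(se {truth_fit.se_beta:.4f}; truth {true_curve.beta})")

ens = ModelEnsemble.from_search(result)
print("\nmodels with likelihood weight >= 0.001:")
for m, w in sorted(ens.reported(), key=lambda mw: -mw[1]):
    print(f"  f={m.transform.f_kind:8s} tau={m.transform.tau} "
          f"mu={m.transform.mu:6.2f}  beta={m.beta_hat:7.4f}  weight={w:.3f}")
print(
    "\nNearly all weight goes to log-type transforms, but it spreads over\n"
    "several (mu, tau) pairs: a larger tau with a lower mu traces almost\n"
    "the same curve as the true (tau=0.1, mu at the median) shape, so the\n"
    "likelihood cannot fully separate them.  That spread is exactly the\n"
    "model-choice uncertainty the ensemble propagates into impact bands."
)
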