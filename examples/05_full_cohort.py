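"""End-to-end synthetic cohort with a planted genotype-by-expansion interaction.

Runs the full pipeline (tumor dynamics -> behavioral gating -> widefield
metrics -> distance bands -> cellular ensembles -> group statistics) on a
reduced two-genotype cohort in which near/far activity gradients steepen
during fast expansion for one genotype only, and prints the comparison
tables that recover this interaction.

The full-size run (3 animals per genotype, 6 sessions) is what
``scripts/acceptance.py`` executes; this example trims sizes for a ~30 s run.
"""

import warnings

from glioscope.pipeline import default_config, run_pipeline

cfg = default_config()
cfg["cohort"]["n_animals_per_genotype"] = 1
cfg["cohort"]["session_days"] = [50, 54, 58, 62]
cfg["cellular"]["n_recordings_per_group"] = 1

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    res = run_pipeline(cfg, "scratch/cohort_example")

print("per-interval tumor dynamics:")
print(res["intervals"][["animal_id", "day_start", "day_end", "cv_per_day",
                        "expansion_rate_um2_per_day", "expansion_class"]]
      .to_string(index=False))

print("\nnear/far ratio means by genotype and expansion class (amplitude):")
print(res["interaction"].to_string(index=False))
print("\nThe 3xCR fast-expansion ratio well above its slow-expansion ratio,"
      "\nwith no such shift for GPC6, is the planted interaction; the"
      "\ncomparison tables in scratch/cohort_example/comparisons.csv test it.")
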