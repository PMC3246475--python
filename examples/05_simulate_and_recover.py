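"""Simulate synthetic cohorts and recover a known spectrum shift.

The generator draws covariates from the study marginals, 0-3 mutations
per participant, and categories from a multinomial logit whose shifts
are true odds ratios.  Here a log(6) shift on CpG transitions in the
hottest-tea stratum is planted and then re-estimated through the full
annotate -> record-unit -> crude-OR chain.
"""

import math

from tp53spectrum import SimulationConfig, recover_parameters, simulate_cohort
from tp53spectrum.synthetic import spectrum_frequencies

cfg = SimulationConfig()  # study scale: 119 participants
cohort = simulate_cohort(cfg, seed=42)
print(f"simulated {len(cohort.participants)} participants, "
      f"{len(cohort.mutation_rows)} mutations, "
      f"{len(set(r.sample_id for r in cohort.ihc_rows))} IHC-evaluable")
freqs = spectrum_frequencies(cohort)
print("category frequencies:",
      {c: round(f, 3) for c, f in sorted(freqs.items()) if f > 0})

true_log_or = math.log(6.0)
big = SimulationConfig(
    n_participants=5000, with_ihc=False,
    effects=(("tea_interval", "0-1", "GC>AT_CpG", true_log_or),),
)
report = recover_parameters(big, "tea_interval", "0-1", "GC>AT_CpG",
                            true_log_or, n_replicates=50, seed=0)
print(f"\nplanted OR 6.0; mean recovered OR "
      f"{math.exp(report['mean_log_or']):.2f} "
      f"(bias {report['bias']:+.3f} on the log scale), "
      f"CI coverage {100 * report['coverage']:.0f}%")

# Near-zero bias and ~95% coverage say the record-unit odds-ratio
# machinery estimates exactly the quantity the generator planted.
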