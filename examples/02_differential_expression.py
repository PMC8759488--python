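"""Per-concentration differential expression against the 0 uM control.

Simulates a 30-gene panel in which 6 genes step up 3-fold at inhibitory
concentrations (>= 0.5 uM), runs the t-test on log2 counts per concentration
with BH correction within each stratum, and prints how many genes reach the
two significance regimes used in practice (BH q < 0.1, raw p < 0.01).
"""

from titracurve import de_table
from titracurve.synthetic import (
    PlantedGeneSpec,
    SigmoidParams,
    SyntheticPanel,
    generate_counts,
)

genes = [
    PlantedGeneSpec(f"hit{i}", "sigmoidal", SigmoidParams(300, 900, 50, 0.3), 0.1)
    for i in range(6)
] + [PlantedGeneSpec(f"null{i}", "flat", 300.0, 0.1) for i in range(24)]
counts, meta, _ = generate_counts(SyntheticPanel(genes=genes, seed=7))

table = de_table(counts, meta, alpha_q=0.1)
print(f"{'conc (uM)':>10s} {'q<0.1':>6s} {'p<0.01':>7s}   (of {counts.shape[0]} genes)")
for conc, sub in table.groupby("concentration_uM"):
    print(
        f"{conc:10g} {int(sub['significant_q'].sum()):6d} "
        f"{int(sub['significant_p01'].sum()):7d}"
    )
print()
print(
    "The planted 3-fold genes become significant only at concentrations at\n"
    "or above their 0.3 uM step; sub-critical doses look like the control."
)
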