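"""Classify concentration-response curves for a small planted panel.

Builds a 6-gene panel with known response shapes over the 7-point
concentration gradient (0-10 uM, 4 replicates, 5% noise), fits the sigmoid
and biphasic models to each gene, and prints the label, direction,
inflection point(s) and whether any inflection falls inside the critical
window (0.05-0.5 uM) that separates regenerative success from failure.
"""

from titracurve import SigmoidParams, BiphasicParams, classify_panel
from titracurve.synthetic import PlantedGeneSpec, SyntheticPanel, generate_counts

genes = [
    PlantedGeneSpec("up_early", "sigmoidal", SigmoidParams(100, 1200, 30, 0.2), 0.05),
    PlantedGeneSpec("up_late", "sigmoidal", SigmoidParams(150, 900, 1.5, 3.0), 0.05),
    PlantedGeneSpec("down_mid", "sigmoidal", SigmoidParams(800, 90, 8, 0.4), 0.05),
    PlantedGeneSpec(
        "bump",
        "biphasic",
        BiphasicParams(
            first=SigmoidParams(40, 600, 120, 0.07),
            second=SigmoidParams(600, 40, 2.5, 2.0),
            mode="product",
            scale=600.0,
        ),
        0.05,
    ),
    PlantedGeneSpec(
        "valley",
        "biphasic",
        BiphasicParams(
            first=SigmoidParams(500, 0, 120, 0.08),
            second=SigmoidParams(60, 560, 2.0, 2.5),
            mode="sum",
        ),
        0.05,
    ),
    PlantedGeneSpec("steady", "flat", 400.0, 0.0),
]
counts, meta, truth = generate_counts(SyntheticPanel(genes=genes, seed=42))

table = classify_panel(counts, meta)
print(f"{'gene':10s} {'label':12s} {'direction':14s} {'inflections (uM)':18s} in_window")
for _, row in table.iterrows():
    print(
        f"{row['gene']:10s} {row['label']:12s} {row['direction']:14s} "
        f"{row['inflection_points']:18s} {row['in_window']}"
    )
print()
print(
    "Genes whose inflection lies in 0.05-0.5 uM switch expression exactly\n"
    "where the regenerative outcome flips, making them candidate outcome\n"
    "determinants.  Near-constant curves short-circuit to 'flat'; note that\n"
    "a noisy no-response gene can instead be absorbed as a low-amplitude\n"
    "fit, so labels should be read together with the fitted range b - a."
)
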