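"""The three bench-assay quantification formulas on worked examples."""

from chipglyco import (
    ChipQpcrRecord,
    CtRecord,
    LuciferaseRecord,
    chip_fold_over_igg,
    ddct_ratio,
    luciferase_relative,
)

# relative expression by 2^-ddCt: target shifted +1 cycle vs control
ratio = ddct_ratio(
    CtRecord("t", "treatment", "FUT4", "target", (25.0,)),
    CtRecord("t", "treatment", "ACTB", "reference", (20.0,)),
    CtRecord("c", "control", "FUT4", "target", (24.0,)),
    CtRecord("c", "control", "ACTB", "reference", (20.0,)),
)
print(f"2^-ddCt ratio: {ratio}")  # 0.5 -> expression halved in treatment

# ChIP-qPCR: a 2-cycle earlier IP Ct means 4-fold enrichment over IgG
fold = chip_fold_over_igg(
    ChipQpcrRecord("F3", "MyoD1", (28.0, 28.2, 27.8)),
    ChipQpcrRecord("F3", "IgG", (30.0, 30.1, 29.9)),
)
print(f"ChIP fold over IgG at fragment F3: {fold:.2f}")

# dual-luciferase: firefly/Renilla per well, relative to the empty vector
rel = luciferase_relative(
    [
        LuciferaseRecord("pGL3", 1000.0, 500.0, 1000.0),
        LuciferaseRecord("Seq1", 620.0, 500.0, 1000.0),
        LuciferaseRecord("Seq2", 1980.0, 490.0, 1000.0),
    ],
    control_id="pGL3",
)
for k, v in rel.items():
    print(f"relative luciferase activity {k}: {v:.2f}")
# values < 1 mean the cloned promoter fragment represses the reporter
# relative to the empty pGL3 control.
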