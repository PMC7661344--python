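"""Small quantification formulas: 2^-ddCt, ChIP-qPCR fold-over-IgG, and
dual-luciferase normalization.

All three are exact arithmetic on cycle thresholds or luminescence
readings. Replicate Ct values are averaged on the Ct scale before any
exponentiation (the conventional order of operations for 2^-ddCt).
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import mean
from typing import Literal


@dataclass(frozen=True)
class CtRecord:
    """qPCR cycle thresholds for one (sample, gene, role)."""

    sample_id: str
    condition: Literal["control", "treatment"]
    gene_id: str
    role: Literal["target", "reference"]
    ct_replicates: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.ct_replicates:
            raise ValueError("need at least one Ct replicate")
        if any(ct <= 0 for ct in self.ct_replicates):
            raise ValueError("Ct values must be positive")

    @property
    def mean_ct(self) -> float:
        return mean(self.ct_replicates)


@dataclass(frozen=True)
class ChipQpcrRecord:
    """Ct values for one immunoprecipitation arm on one promoter fragment."""

    fragment_id: str
    antibody: str  # e.g. "MyoD1" or "IgG"
    ct_replicates: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.ct_replicates:
            raise ValueError("need at least one Ct replicate")
        if any(ct <= 0 for ct in self.ct_replicates):
            raise ValueError("Ct values must be positive")

    @property
    def mean_ct(self) -> float:
        return mean(self.ct_replicates)


@dataclass(frozen=True)
class LuciferaseRecord:
    """Firefly/Renilla luminescence for one reporter construct well."""

    construct_id: str
    firefly: float
    renilla: float
    cell_count: float = 1000.0

    def __post_init__(self) -> None:
        if self.renilla <= 0:
            raise ValueError("Renilla reading must be positive")
        if self.cell_count <= 0:
            raise ValueError("cell count must be positive")


def ddct_ratio(
    target_treated: CtRecord,
    ref_treated: CtRecord,
    target_control: CtRecord,
    ref_control: CtRecord,
) -> float:
    """Relative expression 2^-ddCt.

    dCt = mean Ct(target) - mean Ct(reference) within each condition;
    ddCt = dCt(treated) - dCt(control); the result is the treated/control
    expression ratio of the target gene, normalised to the reference gene.
    """
    for rec, role in (
        (target_treated, "target"),
        (ref_treated, "reference"),
        (target_control, "target"),
        (ref_control, "reference"),
    ):
        if rec.role != role:
            raise ValueError(f"record {rec.sample_id}/{rec.gene_id} is not a {role} record")
    if target_treated.gene_id != target_control.gene_id:
        raise ValueError("target gene mismatch between conditions")
    if ref_treated.gene_id != ref_control.gene_id:
        raise ValueError("reference gene mismatch between conditions")
    dct_treated = target_treated.mean_ct - ref_treated.mean_ct
    dct_control = target_control.mean_ct - ref_control.mean_ct
    ddct = dct_treated - dct_control
    return 2.0 ** (-ddct)


def chip_fold_over_igg(
    ip: ChipQpcrRecord,
    igg: ChipQpcrRecord,
    input_record: ChipQpcrRecord | None = None,
) -> float:
    """ChIP-qPCR enrichment of the specific antibody over the IgG control.

    Without an input record, fold = 2^(meanCt(IgG) - meanCt(IP)). With an
    input record each arm is first expressed as percent input,
    2^(Ct_input - Ct_arm), and the ratio of percent-inputs is returned;
    when the input is shared the two formulations agree exactly.
    """
    if ip.fragment_id != igg.fragment_id:
        raise ValueError(
            f"fragment mismatch: {ip.fragment_id!r} vs {igg.fragment_id!r}"
        )
    if input_record is None:
        return 2.0 ** (igg.mean_ct - ip.mean_ct)
    if input_record.fragment_id != ip.fragment_id:
        raise ValueError("input record is for a different fragment")
    pct_ip = 2.0 ** (input_record.mean_ct - ip.mean_ct)
    pct_igg = 2.0 ** (input_record.mean_ct - igg.mean_ct)
    return pct_ip / pct_igg


def luciferase_relative(
    constructs: list[LuciferaseRecord], control_id: str
) -> dict[str, float]:
    """Firefly/Renilla-normalised reporter activity relative to a control
    construct.

    Each well's firefly and Renilla readings are scaled to 'per 1000 cells'
    (dividing both by cell_count/1000, so the scaling cancels inside a
    well), the firefly/Renilla ratio taken, and every construct divided by
    the control construct's ratio; the control's relative activity is 1.
    """
    by_id = {c.construct_id: c for c in constructs}
    if control_id not in by_id:
        raise ValueError(f"control construct {control_id!r} not present")

    def normalized(c: LuciferaseRecord) -> float:
        per_kilo = c.cell_count / 1000.0
        return (c.firefly / per_kilo) / (c.renilla / per_kilo)

    ctrl = normalized(by_id[control_id])
    return {c.construct_id: normalized(c) / ctrl for c in constructs}
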