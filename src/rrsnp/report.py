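"""Run-report arithmetic: attrition funnels, percentages, chip capacity."""

from __future__ import annotations

from typing import Mapping, Sequence

from .errors import ConfigurationError

FUNNEL_STAGES = (
    "candidates",
    "pass_c1",
    "pass_c2_c5",
    "pass_mask",
    "pass_window",
    "one_per_contig",
)


def primer_eligible(passing_c1_c5: int, masked_out: int) -> int:
    """Loci left for primer design after removing masked sites."""
    if masked_out > passing_c1_c5:
        raise ConfigurationError("masked_out: cannot exceed the passing count")
    return passing_c1_c5 - masked_out


def percent(numerator: float, denominator: float) -> int:
    """Percentage rounded to the nearest whole percent."""
    if denominator == 0:
        raise ConfigurationError("denominator: must be nonzero")
    return int(round(100.0 * numerator / denominator))


def check_attrition_monotone(attrition: Mapping[str, int]) -> bool:
    """True iff each successive funnel stage count <= the previous one."""
    counts = [attrition[stage] for stage in FUNNEL_STAGES if stage in attrition]
    return all(b <= a for a, b in zip(counts, counts[1:]))


def funnel_lines(attrition: Mapping[str, int]) -> Sequence[str]:
    return [f"{stage}: {attrition[stage]}"
            for stage in FUNNEL_STAGES if stage in attrition]
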