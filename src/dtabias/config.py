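"""Run-wide configuration shared by the tests, concordance and pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass(frozen=True)
class RunConfig:
    """Configuration for a full corpus analysis.

    alpha
        Two-sided significance level; calls use strict ``p < alpha``.
    begg_variant
        ``"standardized"`` (Begg-Mazumdar deviates, default) or
        ``"naive"`` (rank-correlate lnDOR with its variance directly).
    continuity
        Constant added to all four cells when any cell is zero.
    min_k
        Minimum number of studies for any asymmetry test.
    low_power_k
        Results from metas with fewer studies carry a low-power note.
    pooling
        ``"dersimonian-laird"`` or ``"fixed"`` for the pooled DOR.
    dor_threshold / dor_threshold_inclusive
        Cut used for the high-DOR moderator (default ``>= 38``).
    """

    alpha: float = 0.05
    begg_variant: str = "standardized"
    continuity: float = 0.5
    min_k: int = 3
    low_power_k: int = 10
    pooling: str = "dersimonian-laird"
    dor_threshold: float = 38.0
    dor_threshold_inclusive: bool = True
    seed: int = 0
    max_funnel_plots: int = 6
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.begg_variant not in ("standardized", "naive"):
            raise ValueError(f"unknown begg_variant {self.begg_variant!r}")
        if self.continuity < 0:
            raise ValueError("continuity must be >= 0")
        if self.min_k < 3:
            raise ValueError("min_k must be >= 3")
        if self.pooling not in ("fixed", "dersimonian-laird"):
            raise ValueError(f"unknown pooling method {self.pooling!r}")
        if self.dor_threshold <= 0:
            raise ValueError("dor_threshold must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)
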