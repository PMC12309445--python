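"""Putative dopamine (DA) vs nondopamine (non-DA) typing of VTA units.

Classification uses two electrophysiological criteria: basal firing rate
below 12 Hz and action-potential waveform duration relative to a 1.2 ms
threshold.  By the convention of optogenetically verified VTA dopamine
neurons, DA units have *wide* waveforms, so the default rule requires
duration >= 1.2 ms for DA; the opposite reading (< 1.2 ms) is available via
``duration_rule="lt"`` for comparison.  Units outside the VTA, or without a
measured waveform, stay untyped.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["CellTypeConfig", "classify_cell_type"]


@dataclass(frozen=True)
class CellTypeConfig:
    rate_max_hz: float = 12.0
    duration_threshold_ms: float = 1.2
    duration_rule: str = "ge"  # "ge": DA if duration >= threshold; "lt": <

    def __post_init__(self) -> None:
        if self.rate_max_hz <= 0 or self.duration_threshold_ms <= 0:
            raise ValueError("cell-typing thresholds must be positive")
        if self.duration_rule not in ("ge", "lt"):
            raise ValueError("duration_rule must be 'ge' or 'lt'")


def classify_cell_type(
    rate_hz: float,
    waveform_ms: float | None,
    cfg: CellTypeConfig = CellTypeConfig(),
    area: str = "VTA",
) -> str:
    """Return "DA", "nonDA" or "untyped" for one unit."""
    if area != "VTA" or waveform_ms is None:
        return "untyped"
    rate_ok = rate_hz < cfg.rate_max_hz
    duration_ok = (
        waveform_ms >= cfg.duration_threshold_ms
        if cfg.duration_rule == "ge"
        else waveform_ms < cfg.duration_threshold_ms
    )
    return "DA" if (rate_ok and duration_ok) else "nonDA"
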