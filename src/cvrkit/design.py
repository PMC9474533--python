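"""Task paradigm and acquisition geometry shared across the pipeline."""
from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class Paradigm:
    """Breath-hold task timing.

    The default is the paced-breathing protocol used throughout the package:
    a lead-in of paced breathing followed by ``n_blocks`` end-expiration
    breath holds of ``hold_s`` seconds, each followed by ``recovery_s``
    seconds of paced breathing.  Breaths are paced at ``breath_period_s``.
    The default lead-in (26 s) makes the total task duration match the
    default 92-volume, TR = 3 s acquisition exactly (276 s).
    """

    n_blocks: int = 5
    hold_s: float = 16.0
    recovery_s: float = 34.0
    lead_in_s: float = 26.0
    breath_period_s: float = 4.0

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        for name in ("hold_s", "recovery_s", "lead_in_s", "breath_period_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def total_duration_s(self) -> float:
        return self.lead_in_s + self.n_blocks * (self.hold_s + self.recovery_s)

    def hold_onsets_s(self) -> list[float]:
        """Start time of each breath-hold block."""
        block = self.hold_s + self.recovery_s
        return [self.lead_in_s + i * block for i in range(self.n_blocks)]

    def hold_ends_s(self) -> list[float]:
        return [t + self.hold_s for t in self.hold_onsets_s()]


@dataclass(frozen=True)
class AcquisitionParams:
    """BOLD acquisition geometry and timing (desk-scale default grid)."""

    tr_s: float = 3.0
    n_volumes: int = 92
    voxel_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    grid_shape: tuple[int, int, int] = (16, 16, 16)

    def __post_init__(self) -> None:
        if self.tr_s <= 0:
            raise ValueError("tr_s must be > 0")
        if self.n_volumes < 2:
            raise ValueError("n_volumes must be >= 2")
        if any(v <= 0 for v in self.voxel_mm):
            raise ValueError("voxel_mm entries must be > 0")

    @property
    def scan_duration_s(self) -> float:
        return self.n_volumes * self.tr_s

    def frame_midpoints_s(self):
        """Acquisition midpoint of each volume, in seconds."""
        import numpy as np

        return (np.arange(self.n_volumes) + 0.5) * self.tr_s

    def covers(self, paradigm: Paradigm) -> bool:
        return self.scan_duration_s >= paradigm.total_duration_s
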