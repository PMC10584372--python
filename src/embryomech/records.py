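"""Time-series records shared by the pulling and patch experiments."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

LOADING, HOLDING, UNLOADING = "loading", "holding", "unloading"


@dataclass
class SimulationRecord:
    """Time series from a load/hold/unload experiment.

    ``displacement`` is the pulled-edge (or load-node) displacement along the
    pull direction in um; ``force`` the applied (constraint) force in nN,
    identically zero during unloading.  ``snapshots`` maps times to full node
    position arrays.  ``extras`` may hold derived series, e.g.
    ``displacement_corotated`` (displacement measured in the best-fit
    rigid-body frame of a free-floating mesh).
    """

    times: np.ndarray
    displacement: np.ndarray
    force: np.ndarray
    phase: np.ndarray  # array of phase labels
    snapshots: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)
    valid: bool = True

    def phase_mask(self, name: str) -> np.ndarray:
        return self.phase == name

    def phase_times(self, name: str) -> np.ndarray:
        return self.times[self.phase_mask(name)]

    def unloading_trace(self, corotated: bool = True):
        """(times, displacement) of the unloading phase, time zeroed at release."""
        m = self.phase_mask(UNLOADING)
        if not m.any():
            raise ValueError("record has no unloading phase")
        disp = self.extras.get("displacement_corotated", self.displacement) if corotated else self.displacement
        t = self.times[m]
        return t - t[0], disp[m]


class InstabilityError(RuntimeError):
    """Raised when a time step moves nodes farther than half a rest length.

    Carries the partial record (flagged invalid) gathered before the abort.
    """

    def __init__(self, message: str, record: SimulationRecord | None = None):
        super().__init__(message)
        self.record = record
        if record is not None:
            record.valid = False
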