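"""Exception types raised by the simulation and calibration layers."""


class EisyncError(Exception):
    """Base class for package-specific failures."""


class IntegrationError(EisyncError):
    """Numerical blow-up (non-finite state) during fixed-step integration.

    Carries the offending step index and cell index so a failing network
    run can be reproduced and inspected.
    """

    def __init__(self, step: int, cell: int, dt: float):
        self.step = step
        self.cell = cell
        self.dt = dt
        super().__init__(
            f"non-finite state at step {step} (t = {step * dt:.3f} ms), "
            f"cell {cell}"
        )


class CalibrationError(EisyncError):
    """The target firing rate could not be bracketed or reached."""


class PrcUndefinedError(EisyncError):
    """Phase response curve requested for a non-periodically-firing neuron."""
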