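"""Exception hierarchy for the stent-design pipeline.

Exit-code mapping used by the CLI: user/input problems (bad files, missing
landmarks, violated constraints) are :class:`UserInputError` subclasses and
map to exit code 2; internal geometry failures (CSG breakdown) map to 3.
"""


class StentForgeError(Exception):
    """Base class for all package errors."""


class UserInputError(StentForgeError):
    """Problems attributable to the caller's inputs (CLI exit code 2)."""


class MeshFormatError(UserInputError):
    """Unreadable, empty, or structurally invalid mesh file."""


class RepairError(UserInputError):
    """Watertight repair failed (too damaged, or degenerate input)."""


class WatertightError(UserInputError):
    """An operation that requires a closed mesh received an open one."""

    def __init__(self, what: str = "mesh"):
        super().__init__(
            f"{what} is not watertight; run repair_watertight() on it first"
        )


class ParameterError(UserInputError):
    """Out-of-range or inconsistent numeric parameter."""


class LandmarkError(UserInputError):
    """A required named landmark is missing from the anatomy model."""

    def __init__(self, name: str):
        self.landmark = name
        super().__init__(f"required landmark {name!r} is missing")


class ScaleError(UserInputError):
    """Articulated pose does not match the configured interincisal opening."""

    def __init__(self, measured_mm: float, expected_mm: float):
        self.measured_mm = float(measured_mm)
        self.expected_mm = float(expected_mm)
        super().__init__(
            f"interincisal distance is {measured_mm:.2f} mm, expected "
            f"{expected_mm:.2f} mm (re-articulate the model or change the config)"
        )


class ConstraintError(UserInputError):
    """A design constraint (e.g. minimum plate thickness) is violated."""


class GeometryError(StentForgeError):
    """Degenerate geometry (rank-deficient point set, plane misses mesh, ...)."""


class CSGError(StentForgeError):
    """Internal boolean/CSG failure (CLI exit code 3)."""

    def __init__(self, message: str, step: str | None = None,
                 checkpoint: str | None = None):
        self.step = step
        self.checkpoint = checkpoint
        if step:
            message = f"[{step}] {message}"
        if checkpoint:
            message += f" (last good checkpoint: {checkpoint})"
        super().__init__(message)
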