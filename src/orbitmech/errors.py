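"""Exception hierarchy shared across the pipeline stages."""


class OrbitmechError(Exception):
    """Base class for all package errors."""


class ValidationError(OrbitmechError):
    """A domain object violates one of its declared invariants."""


class GeometryError(ValidationError):
    """Synthetic anatomy cannot be realized (infeasible geometry)."""


class MissingDistributionError(OrbitmechError):
    """A tissue present in a label volume has no HU distribution."""


class PatchAreaError(OrbitmechError):
    """A requested resection patch cannot be realized on its wall."""


class PatchOverlapError(OrbitmechError):
    """Two non-nested patch tags claim the same boundary face."""


class EmptyTissueError(OrbitmechError):
    """An operation was asked for a tissue with no voxels/elements."""


class MeshError(OrbitmechError):
    """Tetrahedral mesh construction or query failed."""


class UnknownTagError(MeshError):
    """A boundary patch tag is not present on the mesh."""


class DegenerateElementError(MeshError):
    """A tetrahedron has non-positive signed volume."""


class RegistrationError(OrbitmechError):
    """Landmark configuration does not admit a unique rigid transform."""


class SolverError(OrbitmechError):
    """The linear-elastic system could not be solved to tolerance."""


class TetInversionError(OrbitmechError):
    """Displaced elements inverted; the small-strain assumption broke down."""


class CalibrationError(OrbitmechError):
    """Grid-search calibration failed at every sampling point."""


class ReportError(OrbitmechError):
    """A scenario report cannot be built (e.g. zero family maximum)."""


class MissingValueError(OrbitmechError):
    """A clinical record lacks an operand required by the computation."""


class FormatError(OrbitmechError):
    """An on-disk artifact violates its expected format."""
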