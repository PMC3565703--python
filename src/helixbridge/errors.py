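"""Typed errors raised across the package.

Every validation failure raises one of these; callers never receive a
partially constructed object.
"""


class HelixBridgeError(Exception):
    """Base class for all package errors."""


class RaggedAlignmentError(HelixBridgeError):
    """Sequences in an aligned FASTA do not all share the same length."""


class NoSequencesError(HelixBridgeError):
    """An alignment file contained no sequences."""


class RegionOutOfBoundsError(HelixBridgeError):
    """A declared helix region does not fit inside the alignment."""


class InvalidRegionError(HelixBridgeError):
    """A helix region definition is internally inconsistent."""


class EmptyColumnError(HelixBridgeError):
    """An alignment column contains only gaps (or unknowns)."""


class UnknownScaleError(HelixBridgeError):
    """A hydrophobicity scale identifier is not registered."""


class MeasureMismatchError(HelixBridgeError):
    """Two property profiles being compared carry different measures."""


class LagGridMismatchError(HelixBridgeError):
    """Lag scans being combined do not share pairing, helix or lag grid."""


class NoOverlapError(HelixBridgeError):
    """Two helix windows do not overlap under the requested shift."""


class MissingNumberingError(HelixBridgeError):
    """A helix region lacks the reference (.50) column needed for numbering."""


class FixtureSpecError(HelixBridgeError):
    """A synthetic-fixture specification is infeasible."""
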