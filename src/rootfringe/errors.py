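"""Error taxonomy for the pipeline.

Every failure mode that can occur while processing a single image maps to one
of these classes; the batch runner records the stable ``code`` of the raised
class in the per-image status log instead of aborting the run.
"""


class RootFringeError(Exception):
    """Base class for all package errors."""

    code = "error"


class InputError(RootFringeError):
    """Missing, unreadable or structurally invalid input."""

    code = "input"


class LabelConventionError(InputError):
    """A mask contains values outside the {0: background, 1: hair, 2: root} convention."""

    code = "label-convention"


class NoRootError(RootFringeError):
    """The mask contains no root (label 2) pixels."""

    code = "no-root"


class DegenerateRootError(RootFringeError):
    """The root is too small or too short for the requested measurement."""

    code = "degenerate-root"


class GeometryError(RootFringeError):
    """Geometric normalisation failed (e.g. cyclic skeleton with no endpoints)."""

    code = "geometry"


class ModelError(RootFringeError):
    """RFC model misuse: untrained model or feature-configuration mismatch."""

    code = "model"


class SpecificationError(RootFringeError):
    """A synthetic-root specification violates its own invariants."""

    code = "specification"
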