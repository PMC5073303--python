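"""Exception hierarchy for texton3d."""


class Texton3DError(Exception):
    """Base class for all texton3d errors."""


class ParameterError(Texton3DError, ValueError):
    """Invalid parameter value (non-positive sigma, unknown axis, ...)."""


class FormatError(Texton3DError, ValueError):
    """Unreadable or unsupported file contents (e.g. RGB TIFF, missing spacing)."""


class SizeError(Texton3DError, ValueError):
    """Input extents incompatible with the requested operation."""


class ConsistencyError(Texton3DError, ValueError):
    """Mismatched companion objects (response stack vs. bank, histogram vs. dictionary)."""


class DegenerateLibraryError(Texton3DError, ValueError):
    """A training library whose pairwise distances are all zero."""


class StratificationError(Texton3DError, ValueError):
    """A cross-validation split left some class absent from a training partition."""
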