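"""Exception hierarchy shared across the pipeline."""


class PyrosomError(Exception):
    """Base class for all pipeline errors."""


class ParameterError(PyrosomError, ValueError):
    """A parameter violates an operation's precondition."""


class SpectrumError(PyrosomError, ValueError):
    """A spectrum violates its invariants (peak count, ordering, sign)."""


class ParseError(PyrosomError, ValueError):
    """A file could not be parsed; the message names the offending record."""


class EmptyRunError(PyrosomError, ValueError):
    """An mzML file contained no usable MS1 scans."""


class ClassLibraryError(PyrosomError, ValueError):
    """The compound-class table is malformed or inconsistent."""


class UndefinedSimilarityError(PyrosomError, ValueError):
    """Similarity or correlation is undefined (zero vector / zero variance)."""
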