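"""Exception hierarchy shared across the pipeline."""


class ParameterError(ValueError):
    """A configuration value violates its documented constraints."""


class InputError(ValueError):
    """An input object is empty or otherwise unusable."""


class MalformedInputError(ValueError):
    """Structurally inconsistent input (e.g. call/quality length mismatch)."""


class CoordinateError(IndexError):
    """A nucleotide or residue coordinate falls outside the reference."""


class CalibrationError(RuntimeError):
    """A data-derived scale or threshold could not be established."""
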