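"""Exception hierarchy.

``PbviError`` is the base for everything the library raises on bad input;
the CLI maps it to exit code 3 (data error) while usage errors exit 2.
"""


class PbviError(Exception):
    """Base class for all pbvi data and format errors."""


class ModelFormatError(PbviError):
    """A model/counts TSV violates the file format (bad value, duplicate
    position, malformed row). Carries the offending 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class RegionError(PbviError):
    """A BED interval or region request is malformed or refers to a
    chromosome/position absent from the data it is applied to."""


class PileupError(PbviError):
    """Alignment input cannot be counted (missing index, bad header...)."""


class SimulationError(PbviError):
    """A spike/downsample instruction cannot be satisfied."""
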