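"""Exception types shared across the toolkit."""


class CutscanError(Exception):
    """Base class for all toolkit errors."""


class RangeError(CutscanError):
    """A residue or coordinate range falls outside the sequence."""


class UndefinedRatioError(CutscanError):
    """A depletion ratio cannot be formed (zero/negative fluorescence)."""


class MissingControlsError(CutscanError):
    """A plate has no wild-type control records."""


class DegeneratePlateError(CutscanError):
    """Plate control standard deviation is zero; Z-scores are undefined."""


class ParseError(CutscanError):
    """A record in an input file is malformed.

    Carries the 1-based line number when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ConfigError(CutscanError):
    """A required configuration value is missing or inconsistent."""


class UndefinedRateError(CutscanError):
    """A rate is requested over an empty denominator."""


class DegenerateControlError(CutscanError):
    """Background estimate equals 1; the mixture model is unidentifiable."""


class GenerationError(CutscanError):
    """A synthetic-data request cannot be realized (e.g. distance budget)."""
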