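"""Exception hierarchy shared across the pipeline.

Exit-code mapping for the CLI lives in :mod:`flydelay.cli`; library code
raises these types and never calls ``sys.exit``.
"""


class FlyDelayError(Exception):
    """Base class for all package errors."""


class FormatError(FlyDelayError):
    """Malformed input file (bad header, ragged row, illegal value)."""


class ConfigError(FlyDelayError):
    """Invalid configuration (thresholds, fractions, unknown relation)."""


class ConsistencyError(FlyDelayError):
    """Cross-input mismatch (e.g. design sample missing from counts)."""


class EstimationError(FlyDelayError):
    """A statistical estimate cannot be formed from the given data."""


class BatteryError(FlyDelayError):
    """The comparison battery cannot be run (missing sex-age group)."""


class StageError(FlyDelayError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage
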