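"""Exception hierarchy for the replicaseq pipeline.

The CLI maps these onto exit codes: configuration problems exit 2, data and
format problems exit 3.
"""

from __future__ import annotations


class ReplicaseqError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(ReplicaseqError):
    """Invalid configuration: bad group sizes, unknown contrast, bad option."""


class DataError(ReplicaseqError):
    """Input data violates a contract (missing reference gene, bad values)."""


class FormatError(DataError):
    """A file failed to parse; carries file and line provenance."""

    def __init__(self, message: str, path=None, line: int | None = None):
        self.path = str(path) if path is not None else None
        self.line = line
        prefix = ""
        if self.path is not None:
            prefix = self.path
            if line is not None:
                prefix += f":{line}"
            prefix += ": "
        super().__init__(prefix + message)


class StatisticsError(ReplicaseqError):
    """A statistical routine received degenerate input (group too small,
    flat standard curve, constant array profile)."""
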