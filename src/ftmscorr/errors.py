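"""Exception hierarchy for the ftmscorr pipeline."""


class FtmscorrError(Exception):
    """Base class for all package errors."""


class InputError(FtmscorrError):
    """Malformed or empty input data (files, tables, scans)."""


class MzxmlParseError(InputError):
    """mzXML document could not be parsed; message carries the position."""


class PeptideListError(InputError):
    """Peptide-list TSV violates the schema or a row-level invariant."""


class NoPeakError(FtmscorrError):
    """No elution peak found near the hinted retention time."""


class ConvergenceError(FtmscorrError):
    """Iterative correction-function estimation failed to converge."""

    def __init__(self, message: str, last_delta: float | None = None):
        super().__init__(message)
        self.last_delta = last_delta


class NotCorrectableError(FtmscorrError):
    """Profile pair does not satisfy the correction conditions."""
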