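"""Exception hierarchy.

InputError covers malformed user input (sequences, structures, files,
configuration); NumericalError covers tolerance violations in the DFT
coefficient extraction.  The CLI maps these to exit codes 2 and 3.
"""


class RnaScoreDistError(Exception):
    """Base class for all package errors."""


class InputError(RnaScoreDistError):
    """Malformed input: sequence, structure, file or configuration."""


class ScoreBoundError(RnaScoreDistError):
    """An accumulated score exceeded the declared s_max bound."""


class NumericalError(RnaScoreDistError):
    """Numerical tolerance violated during coefficient extraction."""
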