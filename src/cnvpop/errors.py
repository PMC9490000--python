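"""Exception types shared across the pipeline.

Two classes are distinguished so the command-line layer can map them to
distinct exit codes: problems with the *data* handed to an operation
(malformed files, shape mismatches, impossible values) versus problems
with the *parameters* chosen for it (out-of-range thresholds, infeasible
simulation specs).
"""


class InputDataError(ValueError):
    """Raised when an input file or in-memory input violates its contract."""


class ParameterError(ValueError):
    """Raised when a tunable parameter is outside its documented range."""
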