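"""Exception hierarchy shared by all stages.

Validation problems (bad inputs, inconsistent geometry, malformed files) and
compute problems (a stage failing on valid inputs) are kept distinct so the
command line can map them to different exit codes.
"""


class GlymphironError(Exception):
    """Base class for all package errors."""


class ValidationError(GlymphironError):
    """Inputs are malformed or mutually inconsistent (CLI exit code 2)."""


class ComputeError(GlymphironError):
    """A processing stage failed on otherwise valid inputs (CLI exit code 3)."""
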