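"""Exception hierarchy.

``ValidationError`` marks bad inputs or configuration (CLI exit code 2);
``ComputationError`` marks a failure inside an otherwise valid analysis
stage (CLI exit code 3).
"""


class ValidationError(ValueError):
    """Invalid input data or configuration."""


class ComputationError(RuntimeError):
    """An analysis stage failed on valid inputs."""
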