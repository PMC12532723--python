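"""Exception hierarchy shared by all pipeline stages.

``ValidationError`` signals malformed input (schema, dialect, invariant
violations in a simulation spec); ``StatisticalError`` signals data that is
well-formed but does not support the requested computation (too few groups,
zero within-group variance, ...).  The CLI maps these onto exit codes 2 and 3
respectively.
"""


class CrmCertError(Exception):
    """Base class for all errors raised by crmcert."""


class ValidationError(CrmCertError):
    """Input data or configuration violates a declared invariant."""


class StatisticalError(CrmCertError):
    """A statistical precondition of the requested computation fails."""
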