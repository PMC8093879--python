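"""Exception hierarchy shared across the toolkit.

The CLI maps these onto exit codes: validation problems exit 2,
infeasible requests (e.g. more species than the pool holds) exit 3.
"""


class MockbenchError(Exception):
    """Base class for all toolkit errors."""


class ValidationError(MockbenchError, ValueError):
    """Malformed or inconsistent input (bad table, bad profile, bad record)."""


class MissingFieldError(ValidationError):
    """A required metadata field is absent or NaN; the message names the field."""


class InfeasibleError(MockbenchError):
    """A request that the available data cannot satisfy (e.g. a community
    drawing more species than the candidate pool contains)."""


class NoSurvivingGenomesError(MockbenchError):
    """Database curation rejected every input genome."""
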