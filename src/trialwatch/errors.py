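"""Exception hierarchy for the toolkit.

All user-facing failures derive from :class:`TrialWatchError` so the CLI can
map them to a nonzero exit code with a readable message.
"""


class TrialWatchError(Exception):
    """Base class for all toolkit errors."""


class BundleError(TrialWatchError):
    """A mandatory file of an export bundle is missing or unreadable."""


class IntegrityError(TrialWatchError):
    """A snapshot violates referential or temporal integrity.

    Carries the list of findings that triggered the refusal.
    """

    def __init__(self, message, findings=None):
        super().__init__(message)
        self.findings = list(findings or [])


class SchemaError(TrialWatchError):
    """A configuration / instrument file is structurally invalid."""


class FilterError(TrialWatchError):
    """A filter references a centre or visit code absent from the snapshot."""


class FaultSpecError(TrialWatchError):
    """An unknown or malformed fault specification for trial perturbation."""
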