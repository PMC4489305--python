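"""Exception hierarchy.

Data defects discovered during curation are *findings*, not exceptions;
exceptions are reserved for malformed inputs and impossible requests.
"""


class MirHarmonyError(Exception):
    """Base class for all package errors."""


class InvalidSequenceError(MirHarmonyError):
    """A sequence contains characters outside the RNA/DNA alphabet."""


class FormatError(MirHarmonyError):
    """A file does not conform to its declared tabular/FASTA layout."""


class FixtureSpecError(MirHarmonyError):
    """A synthetic-fixture specification is internally impossible."""


class UnknownNamespaceError(MirHarmonyError):
    """A namespace was requested for a version label that is not loaded."""


class UnknownVersionError(MirHarmonyError):
    """A version label is absent from the loaded release series."""


class ConfigurationError(MirHarmonyError):
    """Mutually inconsistent options (e.g. clashing sample ids without prefixing)."""
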