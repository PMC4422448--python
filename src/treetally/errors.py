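"""Exception hierarchy shared across the package."""


class TreetallyError(Exception):
    """Base class for all package-specific errors."""


class DataError(TreetallyError):
    """Malformed or inconsistent input data (bad FASTA, bad coordinates, ...)."""


class TreeError(TreetallyError):
    """Malformed tree input or an operation undefined on the given tree."""


class NoSisterError(TreeError):
    """Raised when a group has no defined sister (not monophyletic within allowance)."""


class SaturationWarning(UserWarning):
    """A pairwise distance hit the correction's domain edge and was capped."""
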