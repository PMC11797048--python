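"""Exception hierarchy.

Validation problems (bad panel files, inconsistent configs) raise
:class:`ValidationError`; problems in genotype data raise :class:`DataError`
subclasses so callers can distinguish "your inputs are malformed" from
"this VCF disagrees with the panel".
"""


class Apol1HapError(Exception):
    """Base class for all package errors."""


class ValidationError(Apol1HapError):
    """Input violates a documented invariant (panel, config, counts...)."""


class PanelError(ValidationError):
    """Malformed or inconsistent variant-panel file."""


class ConfigurationError(ValidationError):
    """A required role tag or policy value is missing/out of domain."""


class DataError(Apol1HapError):
    """Genotype data inconsistent with the panel or the phased-diploid model."""


class MissingSiteError(DataError):
    """A panel variant was not found in the VCF (default missing-site policy)."""


class AlleleMismatchError(DataError):
    """Observed ALT allele at a panel site does not match the panel's alt."""


class UnphasedGenotypeError(DataError):
    """'/'-separated genotype at a panel site under the default policy."""


class MonomorphicSiteError(DataError):
    """LD statistics requested at a locus with allele frequency 0 or 1."""
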