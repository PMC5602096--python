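"""Exception hierarchy.

Every error raised by this package derives from :class:`SynspliceError`, so
callers can catch one type at pipeline boundaries while tests assert the
specific subtype.
"""


class SynspliceError(Exception):
    """Base class for all package errors."""


# --- coordinate / transcript model ---------------------------------------
class VariantNotExonic(SynspliceError):
    """The variant position does not fall inside any exon of the transcript."""


class AmbiguousTranscript(SynspliceError):
    """Variant lies in more than one supplied transcript and none was named."""


class FeatureNotApplicable(SynspliceError):
    """Feature requested for a site class it is not defined for."""


# --- PWM / binding models -------------------------------------------------
class DegenerateMatrix(SynspliceError):
    """A PWM column sums to zero with zero pseudocount."""


class LengthMismatch(SynspliceError):
    """Sequence length does not match the PWM width."""


class InvalidAlphabet(SynspliceError):
    """Sequence contains characters outside {A, C, G, T, U}."""


class WindowTooShort(SynspliceError):
    """Scan window shorter than the PWM width."""


class DegenerateVariance(SynspliceError):
    """Binding or non-binding score variance is zero; Eq-style ratio undefined."""


class IntegrationFailure(SynspliceError):
    """Posterior integration produced a non-finite value."""


# --- splicing-regulatory --------------------------------------------------
class WindowOutOfSequence(SynspliceError):
    """Junction window extends beyond the available sequence."""


class MultipleDifferences(SynspliceError):
    """Reference and alternative sequences differ at more than one position."""


class ProviderUnavailable(SynspliceError):
    """Requested RNA-structure provider cannot be constructed."""


# --- protein --------------------------------------------------------------
class EmptyRange(SynspliceError):
    """Residue range contains no residues."""


# --- cohort / classifier --------------------------------------------------
class ClassEmpty(SynspliceError):
    """A label class required for balancing or splitting is empty."""


class SingleClass(SynspliceError):
    """Training labels contain fewer than two classes."""


class SchemaMismatch(SynspliceError):
    """Feature matrix schema does not match the trained model's schema."""


class AnnotationMissing(SynspliceError):
    """Required annotation could not be resolved for one or more variants."""

    def __init__(self, message, variant_ids=()):
        super().__init__(message)
        self.variant_ids = list(variant_ids)


class DegenerateLabels(SynspliceError):
    """Evaluation requires at least one observation of each label."""


class AllBinsEmpty(SynspliceError):
    """No allele-frequency bin contains any variant."""


# --- simulation / IO ------------------------------------------------------
class Saturation(SynspliceError):
    """More variants requested than available internal exons."""


class ConfigInvalid(SynspliceError):
    """Simulation or run configuration violates an invariant."""


class FormatError(SynspliceError):
    """Malformed input file; message names the offending line/record."""
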