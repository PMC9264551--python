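"""Exception hierarchy for the BBB permeability pipeline.

Every stage raises a named subclass of :class:`BBBUQError` so batch drivers
can catch pipeline errors without swallowing genuine bugs.
"""


class BBBUQError(Exception):
    """Base class for all package errors."""


# --- curation ---------------------------------------------------------------

class UnparseableStructure(BBBUQError):
    """A SMILES string could not be interpreted by the chemistry toolkit."""


class MissingEndpoint(BBBUQError):
    """The labeling mode's endpoint field is absent from the entry."""


class UnrecognizedLabelToken(BBBUQError):
    """An annotated label string is outside the configured vocabulary."""


class MissingColumn(BBBUQError):
    """A required column is absent from an input table."""


class EmptyFile(BBBUQError):
    """An input table contains no data rows."""


# --- featurization ----------------------------------------------------------

class LengthMismatch(BBBUQError):
    """Two aligned vectors have different lengths."""


class EmptyReference(BBBUQError):
    """A nearest-neighbour reference set is empty."""


class MissingPka(BBBUQError):
    """A scoring function requires pKa but none was supplied."""


# --- models -----------------------------------------------------------------

class UnknownPreset(BBBUQError):
    """No model preset is registered under the requested name."""


class SingleClassTraining(BBBUQError):
    """Training labels contain only one class."""


class ShapeMismatch(BBBUQError):
    """Feature matrix and label vector are not row-aligned."""


class DropoutUnsupported(BBBUQError):
    """Dropout inference was requested from a model without dropout."""


class LatentUnsupported(BBBUQError):
    """Latent extraction was requested from a model without hidden layers."""


class DuplicateSeeds(BBBUQError):
    """Replicate training requires distinct seeds."""


# --- uncertainty ------------------------------------------------------------

class TooFewReplicates(BBBUQError):
    """Multi-initialization variance needs at least two replicate models."""


class DimensionMismatch(BBBUQError):
    """Latent matrices have incompatible dimensionality."""


class EntropyMissing(BBBUQError):
    """The modZ combination requires the entropy scorer as anchor."""


# --- evaluation -------------------------------------------------------------

class NonMonotoneEdges(BBBUQError):
    """Bin edges must be strictly increasing."""


class EmptyAfterFilter(BBBUQError):
    """A retention fraction keeps zero predictions."""


class MissingProbabilities(BBBUQError):
    """Ranking metrics (ROC/PRC AUC) require class probabilities."""


# --- synthetic fixtures -----------------------------------------------------

class ExhaustedCombinations(BBBUQError):
    """The requested library size exceeds the enumerable chemical space."""


class UnattainableImbalance(BBBUQError):
    """The requested class balance cannot be reached at the given noise."""
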