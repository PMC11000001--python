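"""Exception hierarchy shared across the package."""


class DrugSignetError(Exception):
    """Base class for all package-specific errors."""


class NetworkParseError(DrugSignetError):
    """A network file row could not be parsed."""


class SignContradictionError(DrugSignetError):
    """Duplicate (source, target) rows carry conflicting signs."""


class EmptyModelError(DrugSignetError):
    """Trimming left no drug-target nodes or no TFs."""


class UndefinedSimilarityError(DrugSignetError):
    """Tanimoto similarity of two all-zero fingerprints is undefined."""


class InfeasibleSplitError(DrugSignetError):
    """No chemically dissimilar train/test split satisfies the constraint."""


class DivergenceError(DrugSignetError):
    """The recurrent state became non-finite during propagation."""


class GenerationError(DrugSignetError):
    """A synthetic fixture could not be generated under the given settings."""
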