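"""Exception hierarchy for the barcoding-gap pipeline.

Input/consistency problems (bad files, mismatched labels, bad coordinates)
derive from :class:`InputError`; conditions where the data are valid but
degenerate for the requested analysis derive from :class:`DegenerateDataError`.
The CLI maps these to exit codes 2 and 3 respectively.
"""

from __future__ import annotations


class BarcodeGapError(Exception):
    """Base class for all package errors."""


class InputError(BarcodeGapError):
    """Malformed or inconsistent user input."""


class AlignmentError(InputError):
    """Sequences do not form a valid alignment (length/alphabet problems)."""


class LabelError(InputError):
    """Sequence ids and the species-label table do not agree."""


class BoundsError(InputError):
    """Alignment-column coordinates out of range."""


class DomainError(InputError):
    """Parameter outside its mathematical domain (e.g. negative threshold)."""


class DegenerateDataError(BarcodeGapError):
    """Data valid but insufficient for the requested computation."""


class EmptyDatasetError(DegenerateDataError):
    """Filtering or input left no sequences to analyse."""


class UndefinedDistanceError(DegenerateDataError):
    """A pairwise distance is undefined (no comparable sites)."""


class SaturationError(UndefinedDistanceError):
    """K2P log argument is non-positive: the pair is saturated.

    Carries the offending transition/transversion proportions.
    """

    def __init__(self, message: str, p: float, q: float):
        super().__init__(message)
        self.p = p
        self.q = q


class NoIntraspecificPairsError(DegenerateDataError):
    """No species has two or more members, so intraspecific distances are empty."""


class SingleSpeciesError(DegenerateDataError):
    """Only one species present: interspecific distances are empty."""


class UndefinedDiversityError(DegenerateDataError):
    """Diversity statistic undefined (e.g. zero usable alignment columns)."""
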