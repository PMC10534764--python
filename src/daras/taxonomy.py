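"""Action taxonomy for in-home depth monitoring.

Six categories are recognized: five clinically relevant upper-extremity /
mobility actions plus a catch-all background class (``none_of_the_above``)
that also absorbs simultaneous mixed actions such as walking while reaching.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class TaxonomyError(ValueError):
    """Raised when a label is not part of the taxonomy."""


@dataclass(frozen=True)
class ActionTaxonomy:
    """Ordered label set with a single designated background class.

    Attributes
    ----------
    labels : tuple of str
        All class names, background included.
    background : str
        The background ("none of the above") label.
    """

    labels: tuple[str, ...]
    background: str = "none_of_the_above"
    _index: dict = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self):
        if self.labels.count(self.background) != 1:
            raise TaxonomyError(
                f"background label {self.background!r} must appear exactly once"
            )
        object.__setattr__(
            self, "_index", {lab: i for i, lab in enumerate(self.labels)}
        )
        if len(self._index) != len(self.labels):
            raise TaxonomyError("duplicate labels in taxonomy")

    @property
    def n_classes(self) -> int:
        """Total number of classes, background included (K + 1)."""
        return len(self.labels)

    @property
    def n_actions(self) -> int:
        """Number of non-background action classes (K)."""
        return len(self.labels) - 1

    @property
    def background_index(self) -> int:
        return self._index[self.background]

    def index(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise TaxonomyError(f"unknown label {label!r}") from None

    def __contains__(self, label: str) -> bool:
        return label in self._index

    def validate(self, labels) -> None:
        for lab in labels:
            if lab not in self._index:
                raise TaxonomyError(f"unknown label {lab!r}")


#: The six in-home activity categories used throughout the package.
DEFAULT_TAXONOMY = ActionTaxonomy(
    labels=(
        "walking",
        "reaching_overhead",
        "reaching_forward",
        "reaching_below_waist",
        "hand_manipulation",
        "none_of_the_above",
    )
)
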