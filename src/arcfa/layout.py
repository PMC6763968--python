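"""Item layouts: names, trait membership, administration order, scoring.

An :class:`ItemLayout` is the structural backbone of every model in this
package.  It records, for each survey item, which latent trait it measures,
where it sits in the administration sequence, and whether it is reverse
scored.  The administration order is what defines the topology of the
autoregressive residual structure: context effects run strictly forward in
time, from earlier-administered items to later ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["Item", "ItemLayout", "minipip_layout"]

NORMAL = "normal"
REVERSED = "reversed"


@dataclass(frozen=True)
class Item:
    """One item descriptor.

    Parameters
    ----------
    name : str
        Unique item name, e.g. ``"e2"``.
    trait : str
        Label of the latent construct the item measures.
    position : int
        1-based administration position.
    scoring : str
        ``"normal"`` or ``"reversed"`` (reverse-keyed wording).
    text : str, optional
        Free-text item stem.
    """

    name: str
    trait: str
    position: int
    scoring: str = NORMAL
    text: str = ""

    def __post_init__(self) -> None:
        if self.scoring not in (NORMAL, REVERSED):
            raise ValueError(f"scoring must be 'normal' or 'reversed', got {self.scoring!r}")


@dataclass(frozen=True)
class ItemLayout:
    """An ordered collection of items with validated structure.

    Invariants enforced at construction: positions are a permutation of
    ``1..p``; names are unique; every trait has at least one item.
    """

    items: tuple[Item, ...]
    # caches, derived in __post_init__
    _by_name: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.items:
            raise ValueError("layout needs at least one item")
        positions = sorted(it.position for it in self.items)
        if positions != list(range(1, len(self.items) + 1)):
            raise ValueError("positions must be a gap-free permutation of 1..p")
        names = [it.name for it in self.items]
        if len(set(names)) != len(names):
            raise ValueError("item names must be unique")
        ordered = tuple(sorted(self.items, key=lambda it: it.position))
        object.__setattr__(self, "items", ordered)
        object.__setattr__(self, "_by_name", {it.name: it for it in ordered})

    # -- basic accessors ---------------------------------------------------
    @property
    def p(self) -> int:
        """Number of items."""
        return len(self.items)

    @property
    def traits(self) -> tuple[str, ...]:
        """Trait labels in order of first administration."""
        seen: list[str] = []
        for it in self.items:
            if it.trait not in seen:
                seen.append(it.trait)
        return tuple(seen)

    @property
    def m(self) -> int:
        """Number of traits."""
        return len(self.traits)

    @property
    def names(self) -> tuple[str, ...]:
        """Item names in administration order."""
        return tuple(it.name for it in self.items)

    def item(self, name: str) -> Item:
        return self._by_name[name]

    def index(self, name: str) -> int:
        """0-based administration index of an item."""
        return self._by_name[name].position - 1

    def trait_index(self, trait: str) -> int:
        return self.traits.index(trait)

    def trait_items(self, trait: str) -> tuple[Item, ...]:
        """Items of one trait in administration order."""
        return tuple(it for it in self.items if it.trait == trait)


# ---------------------------------------------------------------------------
# The mini-IPIP worked example
# ---------------------------------------------------------------------------

# 20-item Big Five short form; traits cycle e, a, c, n, o four times.
# Reverse-keyed stems are marked by the trailing "R" in the item text.
_MINIPIP_ITEMS: list[tuple[str, str, str]] = [
    ("e1", NORMAL, "Am the life of the party"),
    ("a1", NORMAL, "Sympathize with others' feelings"),
    ("c1", NORMAL, "Get chores done right away"),
    ("n1", NORMAL, "Have frequent mood swings"),
    ("o1", NORMAL, "Have a vivid imagination"),
    ("e2", REVERSED, "Don't talk a lot. R"),
    ("a2", REVERSED, "Am not interested in other people's problems. R"),
    ("c2", REVERSED, "Often forget to put things back in their proper place. R"),
    ("n2", REVERSED, "Am relaxed most of the time. R"),
    ("o2", REVERSED, "Am not interested in abstract ideas. R"),
    ("e3", NORMAL, "Talk to a lot of different people at parties"),
    ("a3", NORMAL, "Feel others' emotions"),
    ("c3", NORMAL, "Like order"),
    ("n3", NORMAL, "Get upset easily"),
    ("o3", REVERSED, "Have difficulty understanding abstract ideas. R"),
    ("e4", REVERSED, "Keep in the background. R"),
    ("a4", REVERSED, "Am not really interested in others. R"),
    ("c4", REVERSED, "Make a mess of things. R"),
    ("n4", REVERSED, "Seldom feel blue. R"),
    ("o4", REVERSED, "Do not have a good imagination. R"),
]

_TRAIT_OF = {"e": "E", "a": "A", "c": "C", "n": "N", "o": "O"}


def minipip_layout() -> ItemLayout:
    """The 20-item mini-IPIP layout in administration order.

    Five traits (Extraversion, Agreeableness, Conscientiousness,
    Neuroticism, Openness) administered in a repeating e, a, c, n, o
    cycle, four items per trait, with mixed normal/reversed scoring.
    """
    items = [
        Item(name=name, trait=_TRAIT_OF[name[0]], position=pos, scoring=scoring, text=text)
        for pos, (name, scoring, text) in enumerate(_MINIPIP_ITEMS, start=1)
    ]
    return ItemLayout(items=tuple(items))
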