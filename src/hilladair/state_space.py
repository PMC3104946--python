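"""Particle-number configuration spaces for cooperative ligand binding.

Two reaction schemes for a protein C with ``h`` ligand-binding sites are
considered.  In the Hill scheme all ``h`` ligands A bind in a single step,

    C + h A  <->  C_h,

so a configuration is the triple ``(n0, nh, nA)``: copy numbers of free
protein, fully bound complex and free ligand.  In the Adair-Klotz scheme
ligands bind one at a time through intermediates C_1 .. C_{h-1},

    C_{i-1} + A  <->  C_i,    i = 1..h,

and a configuration is ``(n0, n1, ..., nh, nA)``.

Starting both systems from the pure state with ``P0`` free proteins and
``L0`` free ligands, the reachable spaces are finite.  Every Hill
configuration has a unique image in the Adair-Klotz space (the state with
the same ``n0``, ``nh``, ``nA`` and no intermediates); the images form the
*common state space* on which the two models are compared, and the
remaining Adair-Klotz states (at least one intermediate present) form the
*complement space*.

States are stored as plain integer tuples.  Hill states additionally carry
field names via :class:`HillState`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator, NamedTuple, Sequence

import numpy as np

__all__ = [
    "HillState",
    "EnumeratedSpace",
    "CommonStateMap",
    "enumerate_hill_space",
    "enumerate_adair_space",
    "image_of_hill_state",
    "build_common_state_map",
    "initial_distribution",
]


class HillState(NamedTuple):
    """Hill-model configuration ``(n0, nh, nA)``."""

    n0: int
    nh: int
    nA: int


def _check_count(name: str, value: int, minimum: int = 0) -> int:
    if isinstance(value, bool) or not isinstance(value, (int, np.integer)):
        raise TypeError(f"{name} must be an integer, got {value!r}")
    value = int(value)
    if value < minimum:
        raise ValueError(f"{name} must be >= {minimum}, got {value}")
    return value


def _check_parameters(h: int, P0: int, L0: int) -> tuple[int, int, int]:
    return (
        _check_count("h", h, minimum=1),
        _check_count("P0", P0),
        _check_count("L0", L0),
    )


@dataclass(frozen=True)
class EnumeratedSpace:
    """Ordered, reachable configuration space of one model.

    Parameters
    ----------
    model_kind
        ``"hill"`` or ``"adair"``.
    h, P0, L0
        Hill coefficient and initial protein / ligand copy numbers.
    states
        Ordered tuple of integer configuration tuples.  The order is
        deterministic: Hill states ascend in complex count ``i``; Adair
        states descend lexicographically in the occupancy vector
        ``(n0, ..., nh)``.  Index 0 is always the pure initial state.
    """

    model_kind: str
    h: int
    P0: int
    L0: int
    states: tuple[tuple[int, ...], ...]
    _index: dict[tuple[int, ...], int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        index = {tuple(s): i for i, s in enumerate(self.states)}
        if len(index) != len(self.states):
            raise ValueError("states are not distinct")
        object.__setattr__(self, "_index", index)

    def __len__(self) -> int:
        return len(self.states)

    def __iter__(self) -> Iterator[tuple[int, ...]]:
        return iter(self.states)

    def index_of(self, state: Sequence[int]) -> int:
        """Position of ``state`` in the enumeration (KeyError if absent)."""
        return self._index[tuple(state)]

    def __contains__(self, state: Sequence[int]) -> bool:
        return tuple(state) in self._index

    @property
    def initial_state(self) -> tuple[int, ...]:
        """The pure state: all proteins ligand-free, all ligands free."""
        if self.model_kind == "hill":
            return HillState(self.P0, 0, self.L0)
        return (self.P0,) + (0,) * self.h + (self.L0,)

    def to_json(self) -> str:
        return json.dumps(
            {
                "model": self.model_kind,
                "h": self.h,
                "P0": self.P0,
                "L0": self.L0,
                "states": [list(s) for s in self.states],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "EnumeratedSpace":
        obj = json.loads(text)
        return cls(
            model_kind=obj["model"],
            h=obj["h"],
            P0=obj["P0"],
            L0=obj["L0"],
            states=tuple(tuple(s) for s in obj["states"]),
        )


def enumerate_hill_space(h: int, P0: int, L0: int) -> EnumeratedSpace:
    """Reachable Hill configurations from the pure initial state.

    The dynamics is a one-dimensional birth-death chain in the complex
    count ``i``: state ``i`` is ``(P0 - i, i, L0 - h*i)`` for
    ``i = 0 .. min(P0, L0 // h)``.
    """
    h, P0, L0 = _check_parameters(h, P0, L0)
    i_max = min(P0, L0 // h)
    states = tuple(HillState(P0 - i, i, L0 - h * i) for i in range(i_max + 1))
    return EnumeratedSpace("hill", h, P0, L0, states)


def _occupancy_vectors(total: int, parts: int) -> Iterator[tuple[int, ...]]:
    # Descending lexicographic enumeration of compositions of `total`
    # into `parts` non-negative parts.
    if parts == 1:
        yield (total,)
        return
    for first in range(total, -1, -1):
        for rest in _occupancy_vectors(total - first, parts - 1):
            yield (first,) + rest


def enumerate_adair_space(h: int, P0: int, L0: int) -> EnumeratedSpace:
    """Reachable Adair-Klotz configurations from the pure initial state.

    A state is ``(n0, ..., nh, nA)`` with protein conservation
    ``sum(nj) = P0`` and ligand conservation ``nA = L0 - sum(j * nj)``;
    occupancy vectors whose bound-ligand total exceeds ``L0`` are
    unreachable and excluded.  States are ordered by descending
    lexicographic occupancy vector, which places the pure initial state
    first.
    """
    h, P0, L0 = _check_parameters(h, P0, L0)
    states = []
    for occ in _occupancy_vectors(P0, h + 1):
        bound = sum(j * nj for j, nj in enumerate(occ))
        nA = L0 - bound
        if nA >= 0:
            states.append(occ + (nA,))
    return EnumeratedSpace("adair", h, P0, L0, tuple(states))


def image_of_hill_state(c_H: Sequence[int], h: int) -> tuple[int, ...]:
    """Image of a Hill configuration in the Adair-Klotz space.

    The unique Adair-Klotz state with the same ``(n0, nh, nA)`` and all
    intermediate occupancies zero.
    """
    n0, nh, nA = (int(x) for x in c_H)
    return (n0,) + (0,) * (h - 1) + (nh, nA) if h > 1 else (n0, nh, nA)


@dataclass(frozen=True)
class CommonStateMap:
    """One-to-one pairing of Hill states with their Adair-Klotz images.

    ``pairs[i] = (hill_index, adair_index)`` covers the whole Hill space;
    ``complement_indices`` are the Adair-Klotz states containing at least
    one intermediate, which have no Hill partner.
    """

    pairs: tuple[tuple[int, int], ...]
    complement_indices: tuple[int, ...]

    @property
    def hill_indices(self) -> np.ndarray:
        return np.array([p[0] for p in self.pairs], dtype=int)

    @property
    def adair_image_indices(self) -> np.ndarray:
        return np.array([p[1] for p in self.pairs], dtype=int)


def build_common_state_map(
    hill_space: EnumeratedSpace, adair_space: EnumeratedSpace
) -> CommonStateMap:
    """Pair every Hill state with its image; list the complement states."""
    if (hill_space.h, hill_space.P0, hill_space.L0) != (
        adair_space.h,
        adair_space.P0,
        adair_space.L0,
    ):
        raise ValueError("spaces have different (h, P0, L0) parameters")
    pairs = []
    image_set = set()
    for i, c_H in enumerate(hill_space):
        image = image_of_hill_state(c_H, hill_space.h)
        try:
            j = adair_space.index_of(image)
        except KeyError as exc:  # would indicate an enumeration bug
            raise RuntimeError(
                f"image {image} of Hill state {c_H} missing from Adair space"
            ) from exc
        pairs.append((i, j))
        image_set.add(j)
    complement = tuple(j for j in range(len(adair_space)) if j not in image_set)
    return CommonStateMap(tuple(pairs), complement)


def initial_distribution(space: EnumeratedSpace) -> np.ndarray:
    """Pure initial distribution: unit mass on the all-free configuration."""
    if len(space) == 0:
        raise ValueError("empty state space")
    p = np.zeros(len(space))
    p[space.index_of(space.initial_state)] = 1.0
    return p
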