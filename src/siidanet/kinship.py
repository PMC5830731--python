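"""Kin-term paths and coefficients of relatedness.

Genealogical relationships are recorded as strings of immediate, gendered
kin links walked from ego to alter: ``M`` (mother), ``F`` (father),
``B`` (brother), ``Z`` (sister), ``S`` (son), ``D`` (daughter). A brother is
``"B"``; a father's brother's son (a first cousin) is ``"FBS"``. The
coefficient of relatedness for a path of *k* links is ``r = 1/2**k``, so a
sibling or a parent scores 1/2, an uncle 1/4, a first cousin 1/8, and the
empty path (self) scores 1.

Siblings are treated as full siblings (a single link); the path grammar has
no token for half-siblings or for affinal (marriage) links, so those default
to unrelated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "KIN_ALPHABET",
    "KinPathError",
    "parse_kin_path",
    "relatedness",
    "RelatednessMatrix",
    "build_relatedness_matrix",
]

logger = logging.getLogger(__name__)

#: Allowed kin-link letters: mother, father, brother, sister, son, daughter.
KIN_ALPHABET = frozenset("MFBZSD")


class KinPathError(ValueError):
    """Raised when a kin-path string contains a letter outside the grammar."""


def parse_kin_path(path: str) -> int:
    """Validate a kin path and return its link count ``k``.

    The empty string denotes self (``k = 0``).

    Raises
    ------
    KinPathError
        If any character is outside ``{M, F, B, Z, S, D}``; the message
        names the offending character and its (0-based) position.
    """
    if not isinstance(path, str):
        raise KinPathError(f"kin path must be a string, got {type(path).__name__}")
    for pos, ch in enumerate(path):
        if ch not in KIN_ALPHABET:
            raise KinPathError(
                f"invalid kin-link character {ch!r} at position {pos} in path {path!r}; "
                f"allowed letters are M, F, B, Z, S, D"
            )
    return len(path)


def relatedness(path: str) -> float:
    """Coefficient of relatedness ``r = 1/2**k`` for a kin path.

    ``""`` (self) gives 1.0, ``"B"`` gives 0.5, ``"FBS"`` gives 0.125.
    """
    k = parse_kin_path(path)
    return 0.5**k


@dataclass
class RelatednessMatrix:
    """Symmetric dyadic relatedness coefficients on a fixed roster ordering.

    Attributes
    ----------
    ids : list of str
        Node identifiers, fixing row/column order.
    values : ndarray
        Square symmetric array with unit diagonal; entries in [0, 1].
    """

    ids: list[str]
    values: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("values must be square with one row per id")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("relatedness matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 1.0):
            raise ValueError("relatedness diagonal must be 1")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("relatedness entries must lie in [0, 1]")
        self._index = {i: k for k, i in enumerate(self.ids)}

    def get(self, ego: str, alter: str) -> float:
        return float(self.values[self._index[ego], self._index[alter]])

    def to_frame(self) -> pd.DataFrame:
        """Long-format (ego, alter, r) table of all off-diagonal entries."""
        rows = [
            (self.ids[i], self.ids[j], self.values[i, j])
            for i in range(len(self.ids))
            for j in range(len(self.ids))
            if i != j
        ]
        return pd.DataFrame(rows, columns=["ego", "alter", "r"])


def build_relatedness_matrix(roster, kin_table: pd.DataFrame, default: float = 0.0) -> RelatednessMatrix:
    """Assemble the dyadic relatedness matrix from reported kin paths.

    Parameters
    ----------
    roster : Roster
        Defines the node universe and ordering.
    kin_table : DataFrame
        Columns ``ego``, ``alter``, ``path``; one reported path per row.
    default : float
        Relatedness assigned to dyads with no reported path (0 = unrelated).

    Both directions of a dyad may be reported. If the two reports imply
    different coefficients, the larger one is kept and a warning is logged:
    keeping the closer relationship is conservative toward detecting kin
    effects, and the conflict is flagged for audit rather than silently
    averaged.
    """
    ids = list(roster.ids)
    index = {i: k for k, i in enumerate(ids)}
    n = len(ids)
    values = np.full((n, n), float(default))
    np.fill_diagonal(values, 1.0)

    for row in kin_table.itertuples(index=False):
        ego, alter, path = str(row.ego), str(row.alter), str(row.path)
        for who in (ego, alter):
            if who not in index:
                raise KeyError(f"id {who!r} in kin table does not appear in the roster")
        if ego == alter:
            continue
        r = relatedness(path)
        i, j = index[ego], index[alter]
        existing = values[i, j]
        if existing not in (float(default), r) and not np.isclose(existing, r):
            kept = max(existing, r)
            logger.warning(
                "conflicting relatedness reports for dyad (%s, %s): %g vs %g; keeping %g",
                ego, alter, existing, r, kept,
            )
            r = kept
        else:
            r = max(existing, r) if existing != float(default) else r
        values[i, j] = r
        values[j, i] = r

    return RelatednessMatrix(ids=ids, values=values)
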