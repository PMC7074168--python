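"""Pedigree container and validation.

A pedigree is an ordered list of (animal, sire, dam) records in which parents
precede their offspring and unknown parents are coded as missing. The ordering
requirement is what makes the tabular relationship method and the
Meuwissen-Luo inbreeding recursion single-pass.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DataFormatError

UNKNOWN = -1  # internal integer code for an unknown parent


@dataclass
class Pedigree:
    """Ordered pedigree with optional per-animal genotyped flags.

    Parameters
    ----------
    ids : sequence of str
        Animal identifiers, unique, ordered parents-first.
    sire : ndarray of int
        Positional index of each animal's sire, or ``UNKNOWN`` (-1).
    dam : ndarray of int
        Positional index of each animal's dam, or ``UNKNOWN`` (-1).
    genotyped : ndarray of bool, optional
        Flag per animal; defaults to all False.
    """

    ids: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    genotyped: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        n = len(self.ids)
        if self.genotyped is None:
            self.genotyped = np.zeros(n, dtype=bool)
        self.genotyped = np.asarray(self.genotyped, dtype=bool)
        if len(set(self.ids.tolist())) != n:
            raise ConfigurationError("pedigree ids are not unique")
        for name, parent in (("sire", self.sire), ("dam", self.dam)):
            if parent.shape != (n,):
                raise ConfigurationError(f"{name} index length != number of animals")
            bad = np.nonzero((parent != UNKNOWN) & ((parent < 0) | (parent >= n)))[0]
            if bad.size:
                raise ConfigurationError(
                    f"animal {self.ids[bad[0]]!r} has out-of-range {name} index"
                )
            later = np.nonzero((parent != UNKNOWN) & (parent >= np.arange(n)))[0]
            if later.size:
                raise ConfigurationError(
                    f"animal {self.ids[later[0]]!r}: {name} does not precede it "
                    "(pedigree must be ordered parents-first; self-ancestry is a cycle)"
                )

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_genotyped(self) -> int:
        return int(self.genotyped.sum())

    @property
    def genotyped_index(self) -> np.ndarray:
        """Positional indices of genotyped animals, in pedigree order."""
        return np.nonzero(self.genotyped)[0]

    def index_of(self, ids) -> np.ndarray:
        """Positional indices of the given animal ids (error on unknown id)."""
        lookup = {a: i for i, a in enumerate(self.ids)}
        try:
            return np.array([lookup[a] for a in ids], dtype=np.int64)
        except KeyError as exc:
            raise ConfigurationError(f"animal {exc.args[0]!r} not in pedigree") from None

    def inbreeding(self) -> np.ndarray:
        """Inbreeding coefficients F by the Meuwissen-Luo (1992) recursion."""
        from .relationship import _meuwissen_luo_inbreeding

        return _meuwissen_luo_inbreeding(self.sire, self.dam)

    def to_frame(self) -> pd.DataFrame:
        """Pedigree as a DataFrame with '0' for unknown parents."""
        def name(idx: np.ndarray) -> np.ndarray:
            out = np.where(idx == UNKNOWN, "0", self.ids[np.clip(idx, 0, None)])
            return out

        return pd.DataFrame(
            {"id": self.ids, "sire": name(self.sire), "dam": name(self.dam),
             "genotyped": self.genotyped.astype(int)}
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, genotyped_ids=None) -> "Pedigree":
        """Build from a DataFrame with columns id, sire, dam (0/NA = unknown).

        Records may be in any order; they are sorted parents-first if needed.
        """
        df = frame.copy()
        for col in ("id", "sire", "dam"):
            if col not in df.columns:
                raise DataFormatError(f"pedigree table lacks required column {col!r}")
            df[col] = df[col].astype(str)
        ids = df["id"].to_numpy(dtype=object)
        known = set(ids.tolist())
        missing_codes = {"0", "", "NA", "nan", "None", ".", "-1"}

        def parent_name(x: str) -> str | None:
            return None if x in missing_codes or x not in known else x

        parents = {
            a: (parent_name(s), parent_name(d))
            for a, s, d in zip(ids, df["sire"], df["dam"])
        }
        order = _topological_order(ids, parents)
        lookup = {a: i for i, a in enumerate(order)}
        sire = np.array(
            [lookup[parents[a][0]] if parents[a][0] else UNKNOWN for a in order]
        )
        dam = np.array(
            [lookup[parents[a][1]] if parents[a][1] else UNKNOWN for a in order]
        )
        genotyped = None
        if genotyped_ids is not None:
            gset = {str(g) for g in genotyped_ids}
            genotyped = np.array([a in gset for a in order])
        elif "genotyped" in df.columns:
            flag = dict(zip(df["id"], df["genotyped"].astype(int)))
            genotyped = np.array([bool(flag[a]) for a in order])
        return cls(np.array(order, dtype=object), sire, dam, genotyped)


def _topological_order(ids, parents) -> list:
    """Parents-first ordering; raises naming a cycle member if one exists."""
    order: list = []
    state: dict = {}  # 0 visiting, 1 done

    for root in ids:
        if state.get(root) == 1:
            continue
        stack = [(root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                state[node] = 1
                order.append(node)
                continue
            if state.get(node) == 1:
                continue
            if state.get(node) == 0:
                raise ConfigurationError(
                    f"pedigree contains a cycle through animal {node!r}"
                )
            state[node] = 0
            stack.append((node, True))
            for p in parents[node]:
                if p is not None and state.get(p) != 1:
                    stack.append((p, False))
    return order
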