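"""Drug response gene (DRG) selection from per-compound signatures.

Each compound carries one or more ranked differential-expression
profiles (dose/time variants of the same perturbation). A drug
signature is the k most up- or down-regulated genes of one profile; k
is swept over a grid matched to the size of the disease module it will
be scored against (within ±500 genes by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .disease import RankedExpressionProfile

logger = logging.getLogger(__name__)

__all__ = ["CompoundProfile", "DrugSignature", "select_drg", "k_grid",
           "load_compound_dir", "load_compound_long_tsv"]


@dataclass(frozen=True)
class CompoundProfile:
    """One expression profile (dose/time variant) of one compound."""

    compound_id: str
    profile_id: str
    ranks: RankedExpressionProfile

    def __len__(self) -> int:
        return len(self.ranks)


@dataclass(frozen=True)
class DrugSignature:
    """The k most up- or down-regulated genes of one compound profile."""

    compound_id: str
    profile_id: str
    direction: str           # 'up' or 'down' (regulated by the drug)
    genes: tuple[str, ...]   # rank order, most extreme first

    def __post_init__(self):
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in drug signature")
        if self.direction not in ("up", "down"):
            raise ValueError(f"bad direction {self.direction!r}")

    @property
    def k_used(self) -> int:
        return len(self.genes)


def select_drg(profile: CompoundProfile, k: int, direction: str) -> DrugSignature:
    """Top-k (up) or bottom-k (down) genes of a compound profile.

    Rank ties are broken by gene identifier so the selection is
    deterministic and platform-independent; signatures are nested in k.
    """
    genes = profile.ranks.top(k, direction)
    return DrugSignature(profile.compound_id, profile.profile_id,
                         direction, tuple(genes))


def k_grid(mag_size: int, step: int = 100, floor: int = 100,
           window: int = 500) -> list[int]:
    """DRG sizes matched to a disease-module size.

    Multiples of ``step`` within ``[max(floor, mag_size - window),
    mag_size + window]`` (upper bound aligned downward). A module of 500
    genes therefore yields k in {100, 200, ..., 1000}. The floor keeps
    signatures from degenerating for very small modules.
    """
    if mag_size < 1:
        raise ValueError("mag_size must be >= 1")
    lo = max(floor, mag_size - window)
    hi = mag_size + window
    first = -(-lo // step) * step          # align lo upward
    ks = list(range(first, hi + 1, step))
    if not ks:                             # window narrower than step
        ks = [max(floor, -(-mag_size // step) * step)]
    return ks


def load_compound_dir(path: str | Path) -> list[CompoundProfile]:
    """Load a directory of ``<compound>__<profile>.tsv`` rank tables."""
    path = Path(path)
    profiles = []
    for f in sorted(path.glob("*.tsv")):
        stem = f.stem
        if "__" not in stem:
            raise ValueError(
                f"{f}: file name must look like <compound>__<profile>.tsv")
        compound, profile_id = stem.split("__", 1)
        profiles.append(CompoundProfile(
            compound, profile_id, RankedExpressionProfile.from_tsv(f)))
    return profiles


def load_compound_long_tsv(path: str | Path) -> list[CompoundProfile]:
    """Load a long-format table: compound, profile, gene, statistic."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["compound", "profile", "gene", "stat"],
                     dtype={"compound": str, "profile": str, "gene": str})
    out = []
    for (cid, pid), grp in df.groupby(["compound", "profile"], sort=True):
        out.append(CompoundProfile(
            cid, pid,
            RankedExpressionProfile(tuple(grp["gene"]),
                                    tuple(grp["stat"].astype(float)))))
    return out
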