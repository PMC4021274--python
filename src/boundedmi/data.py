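"""Core containers for complete datasets and their imputation design matrix.

A complete dataset bundles one bounded score (e.g. a GHQ summary at the
incomplete wave), a fully observed binary outcome and a fully observed
4-level ordinal auxiliary variable. The score is the only variable that is
ever set to missing; the outcome and auxiliary always enter the imputation
model complete.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

#: Ordered labels of the 4-level auxiliary variable (reference level first).
AUX_LEVELS = ("low", "moderate", "high", "very_high")


@dataclass(frozen=True)
class CompleteDataset:
    """A fully observed dataset: bounded score, binary outcome, ordinal auxiliary.

    Parameters
    ----------
    score
        Bounded score values, ``lo <= score_i <= hi`` for all i.
    outcome
        Binary (0/1) outcome vector, fully observed.
    aux
        Auxiliary variable coded 0..3 (``low`` .. ``very_high``), fully observed.
    lo, hi
        Hard range limits of the score.
    """

    score: np.ndarray
    outcome: np.ndarray
    aux: np.ndarray
    lo: float
    hi: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "score", np.asarray(self.score, dtype=float))
        object.__setattr__(self, "outcome", np.asarray(self.outcome, dtype=int))
        object.__setattr__(self, "aux", np.asarray(self.aux, dtype=int))
        n = self.score.shape[0]
        if self.outcome.shape[0] != n or self.aux.shape[0] != n:
            raise ValueError("score, outcome and aux must have equal length")
        if not self.lo < self.hi:
            raise ValueError("require lo < hi")
        if np.any(~np.isfinite(self.score)):
            raise ValueError("complete dataset may not contain missing scores")
        if self.score.min() < self.lo or self.score.max() > self.hi:
            raise ValueError("score values outside [lo, hi]")
        if not np.isin(self.outcome, [0, 1]).all():
            raise ValueError("outcome must be binary 0/1")
        if not np.isin(self.aux, range(len(AUX_LEVELS))).all():
            raise ValueError("aux codes must lie in 0..3")

    @property
    def n(self) -> int:
        return self.score.shape[0]


def design_matrix(outcome: np.ndarray, aux: np.ndarray) -> np.ndarray:
    """Imputation-model design matrix: intercept, outcome, 3 auxiliary dummies.

    The auxiliary variable enters as indicator columns for ``moderate``,
    ``high`` and ``very_high`` with ``low`` as the reference level, mirroring
    how it appears in the missingness model.
    """
    outcome = np.asarray(outcome, dtype=float)
    aux = np.asarray(aux, dtype=int)
    n = outcome.shape[0]
    X = np.empty((n, 5))
    X[:, 0] = 1.0
    X[:, 1] = outcome
    for j in (1, 2, 3):
        X[:, 1 + j] = aux == j
    return X


def write_dataset(data: CompleteDataset, path: str | Path,
                  mask: np.ndarray | None = None,
                  profile: str | None = None) -> None:
    """Write a dataset as a headered CSV plus a YAML metadata sidecar.

    Masked score cells (``mask`` true) are written empty; the mask itself is
    stored as an extra 0/1 ``missing`` column when given.
    """
    path = Path(path)
    score = data.score.astype(object)
    cols = {"score": score, "outcome": data.outcome,
            "aux": [AUX_LEVELS[a] for a in data.aux]}
    if mask is not None:
        cols["score"] = np.where(mask, np.nan, data.score)
        cols["missing"] = np.asarray(mask, dtype=int)
    pd.DataFrame(cols).to_csv(path, index=False)
    meta = {"lo": float(data.lo), "hi": float(data.hi), "n": int(data.n)}
    if profile is not None:
        meta["profile"] = profile
    path.with_suffix(".meta.yaml").write_text(yaml.safe_dump(meta))


def read_dataset(path: str | Path) -> tuple[CompleteDataset, np.ndarray | None]:
    """Read a dataset written by :func:`write_dataset`.

    Returns the dataset and, if the table carries missing score cells, the
    boolean missingness mask (masked scores are filled with ``lo`` in the
    returned container; use the mask to identify them).
    """
    path = Path(path)
    df = pd.read_csv(path)
    meta_path = path.with_suffix(".meta.yaml")
    if meta_path.exists():
        meta = yaml.safe_load(meta_path.read_text())
        lo, hi = float(meta["lo"]), float(meta["hi"])
    else:
        lo, hi = float(df["score"].min()), float(df["score"].max())
    aux = np.array([AUX_LEVELS.index(a) for a in df["aux"]])
    score = df["score"].to_numpy(dtype=float)
    mask: np.ndarray | None = None
    if "missing" in df.columns:
        mask = df["missing"].to_numpy(dtype=bool)
    elif np.isnan(score).any():
        mask = np.isnan(score)
    if mask is not None:
        score = np.where(mask, lo, score)
    data = CompleteDataset(score=score, outcome=df["outcome"].to_numpy(),
                           aux=aux, lo=lo, hi=hi)
    return data, mask


def as_rng(seed: int | np.random.Generator | np.random.SeedSequence | None
           ) -> np.random.Generator:
    """Coerce a seed, SeedSequence or Generator into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
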