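"""Double-entered DeFries-Fulker regression designs.

The DF method regresses one twin's score (K1) on the co-twin's score
(K2), genetic relatedness (R = 1.0 for MZ, 0.5 for DZ) and their
interaction.  Three equation variants are supported:

- ``eq1``: K1 ~ b0 + b1*K2 + b2*R + b3*(R x K2)         (classical form)
- ``eq2``: K1 ~ b0 + b1*(K2-Km) + b2*[R x (K2-Km)]      (mean-centered)
- ``eq3``: eq2 plus one slope per within-pair difference score (ENVDIF)

where Km is the mean of K2 over the analysis rows.  Under ``eq2``/``eq3``
b1 estimates the shared-environmental variance share (c2) and b2 the
heritability (h2).

Each usable pair is entered twice, once with each member as the focal
twin; ENVDIF columns (focal minus co-twin on a measured covariate) are
therefore antisymmetric across a pair's two rows and sum to zero.
Pairs with unknown zygosity or any missing model variable are dropped
whole (listwise deletion at the pair level) and the exclusions logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DFModelSpec",
    "RankDeficiencyError",
    "compute_r",
    "double_enter",
    "center_cotwin",
    "build_design",
]

RELATEDNESS = {"MZ": 1.0, "DZ": 0.5}


class RankDeficiencyError(ValueError):
    """Design matrix is rank deficient; names the collinear columns."""

    def __init__(self, columns: Sequence[str]):
        self.columns = [str(c) for c in columns]
        super().__init__(
            "design matrix is rank deficient; collinear columns: "
            + ", ".join(self.columns)
        )


@dataclass(frozen=True)
class DFModelSpec:
    """Equation variant plus the ENVDIF covariates it includes."""

    variant: str = "eq2"
    envdif: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.variant not in ("eq1", "eq2", "eq3"):
            raise ValueError(f"unknown DF variant {self.variant!r}")
        object.__setattr__(self, "envdif", tuple(self.envdif))
        if self.variant == "eq3" and not self.envdif:
            raise ValueError("eq3 requires at least one ENVDIF covariate")
        if self.variant != "eq3" and self.envdif:
            raise ValueError(f"{self.variant} takes no ENVDIF covariates")


def compute_r(zygosity: str) -> float:
    """Genetic-relatedness coefficient: MZ -> 1.0, DZ -> 0.5.

    Any other kinship label raises ``KeyError``; such pairs are excluded
    upstream (e.g. undetermined zygosity).
    """
    try:
        return RELATEDNESS[zygosity]
    except KeyError:
        raise KeyError(
            f"unsupported zygosity {zygosity!r}; DF analysis requires MZ or DZ pairs"
        ) from None


def double_enter(
    pairs: pd.DataFrame,
    envdif: Sequence[str] = (),
    outcome: str = "outcome",
    pair_id: str = "pair_id",
    zygosity: str = "zygosity",
) -> pd.DataFrame:
    """Build the double-entered analysis rows from a one-row-per-twin table.

    Each complete pair contributes two rows: (K1 = member i's outcome,
    K2 = co-twin's outcome) for i = 1, 2, with ``envdif_<name>`` columns
    holding focal-minus-co-twin differences for each requested covariate.
    Pairs are dropped whole — with a logged count per reason — when the
    zygosity is not MZ/DZ, the pair does not have exactly two members, or
    either member is missing the outcome or a requested covariate.
    """
    envdif = list(envdif)
    needed = [pair_id, zygosity, outcome] + envdif
    missing_cols = [c for c in needed if c not in pairs.columns]
    if missing_cols:
        raise KeyError(f"columns missing from twin table: {missing_cols}")

    df = pairs[needed].copy()
    sizes = df.groupby(pair_id, sort=False)[outcome].size()
    bad_size = sizes.index[sizes != 2]
    if len(bad_size):
        logger.warning("dropping %d pairs without exactly two members", len(bad_size))
        df = df[~df[pair_id].isin(bad_size)]

    zyg = df.groupby(pair_id, sort=False)[zygosity].first()
    unknown = zyg.index[~zyg.isin(RELATEDNESS)]
    if len(unknown):
        logger.warning(
            "excluding %d pairs of undetermined/unsupported zygosity", len(unknown)
        )
        df = df[~df[pair_id].isin(unknown)]

    incomplete = df[pair_id][df[[outcome] + envdif].isna().any(axis=1)].unique()
    if len(incomplete):
        logger.info(
            "listwise deletion: dropping %d pairs with missing model variables",
            len(incomplete),
        )
        df = df[~df[pair_id].isin(incomplete)]
    if not len(df):
        raise ValueError("no complete MZ/DZ pairs remain after exclusions")

    # pair-major layout: member arrays of shape (n_pairs, 2)
    df = df.sort_values(pair_id, kind="stable")
    ids = df[pair_id].to_numpy()[::2]
    y = df[outcome].to_numpy(dtype=float).reshape(-1, 2)
    r = df[zygosity].map(RELATEDNESS).to_numpy(dtype=float)[::2]

    rows = pd.DataFrame(
        {
            "pair_id": np.repeat(ids, 2),
            "K1": y.ravel(),
            "K2": y[:, ::-1].ravel(),
            "R": np.repeat(r, 2),
        }
    )
    for name in envdif:
        x = df[name].to_numpy(dtype=float).reshape(-1, 2)
        rows[f"envdif_{name}"] = (x - x[:, ::-1]).ravel()
    return rows


def center_cotwin(rows: pd.DataFrame) -> pd.DataFrame:
    """Add ``K2_centered`` = K2 - Km, with Km the mean of K2 over the rows.

    Km is computed on the analysis sample actually entering the model
    (after listwise deletion), so each fitted model is self-contained.
    """
    if not len(rows):
        raise ValueError("cannot center an empty row set")
    out = rows.copy()
    out["K2_centered"] = rows["K2"] - rows["K2"].mean()
    return out


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank == X.shape[1]:
        return
    # identify a minimal set of offending columns via pivoted QR
    from scipy.linalg import qr

    _, Rq, piv = qr(arr, mode="economic", pivoting=True)
    diag = np.abs(np.diag(Rq))
    tol = diag.max() * max(arr.shape) * np.finfo(float).eps if diag.size else 0.0
    dropped = [X.columns[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
    raise RankDeficiencyError(dropped or list(X.columns))


def build_design(rows: pd.DataFrame, spec: DFModelSpec):
    """Assemble the design matrix and response for one DF equation.

    Returns ``(X, y)`` with named columns: ``eq1`` -> intercept, K2, R,
    R_x_K2; ``eq2`` -> intercept, K2_centered, R_x_K2_centered; ``eq3`` ->
    eq2 columns plus ``envdif_<name>`` in spec order.  Raises
    :class:`RankDeficiencyError` when the columns are collinear (e.g.
    single-zygosity data, where R is constant).
    """
    X = pd.DataFrame(index=rows.index)
    X["intercept"] = 1.0
    if spec.variant == "eq1":
        X["K2"] = rows["K2"]
        X["R"] = rows["R"]
        X["R_x_K2"] = rows["R"] * rows["K2"]
    else:
        if "K2_centered" not in rows.columns:
            rows = center_cotwin(rows)
            X = X.set_axis(rows.index)
        X["K2_centered"] = rows["K2_centered"]
        X["R_x_K2_centered"] = rows["R"] * rows["K2_centered"]
        for name in spec.envdif:
            col = f"envdif_{name}"
            if col not in rows.columns:
                raise KeyError(f"ENVDIF covariate {name!r} not present in design rows")
            X[col] = rows[col]
    y = rows["K1"].astype(float)
    if len(X) < X.shape[1]:
        raise ValueError(f"{len(X)} rows cannot identify {X.shape[1]} coefficients")
    _check_rank(X)
    return X, y
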