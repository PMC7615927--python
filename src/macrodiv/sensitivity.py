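"""Sensitivity of diversity estimates and downstream inference to the number
of sequences per species.

Small per-species sample sizes make nucleotide diversity noisy.  The module
quantifies that noise by resampling sequences with replacement at sample
sizes 2..10 (100 replicates each) and tabulating the replicate variance, and
re-runs the regression after imposing a minimum-sequence cutoff with the
median resampled diversity as the response.
"""

from __future__ import annotations

from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

from .betareg import BetaRegression, BetaRegressionResults
from .predictors import DesignMatrix, assemble_design
from .seqstats import AlignedSeqSet, nucleotide_diversity

__all__ = [
    "resample_diversity",
    "resample_table",
    "variance_by_size",
    "median_diversity",
    "cutoff_rerun",
]


def resample_diversity(
    aln: AlignedSeqSet,
    sizes: Iterable[int] = range(2, 11),
    reps: int = 100,
    seed: int | np.random.Generator = 0,
    deletion_mode: str = "complete",
) -> pd.DataFrame:
    """Bootstrap nucleotide diversity at each sample size.

    For each m in ``sizes`` draw m sequences with replacement, compute pi,
    repeat ``reps`` times.  Returns tidy rows (species_id, m, replicate, pi).
    Resampling with replacement is valid for any alignment with n >= 2.
    """
    if aln.n < 2:
        raise ValueError("need at least 2 sequences")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for m in sizes:
        for r in range(reps):
            idx = rng.integers(0, aln.n, int(m))
            sub = AlignedSeqSet(aln.species_id, tuple(aln.ids[i] for i in idx), aln.matrix[idx])
            rows.append(
                {
                    "species_id": aln.species_id,
                    "m": int(m),
                    "replicate": r + 1,
                    "pi": nucleotide_diversity(sub, deletion_mode),
                }
            )
    return pd.DataFrame(rows)


def resample_table(
    alignments: Mapping[str, AlignedSeqSet],
    sizes: Iterable[int] = range(2, 11),
    reps: int = 100,
    seed: int = 0,
    deletion_mode: str = "complete",
) -> pd.DataFrame:
    """Resampled diversity for every species (one substream per species, so
    per-species results do not depend on iteration order)."""
    ss = np.random.SeedSequence(seed)
    keys = sorted(alignments)
    out = []
    for key, child in zip(keys, ss.spawn(len(keys))):
        out.append(
            resample_diversity(
                alignments[key], sizes, reps, np.random.default_rng(child), deletion_mode
            )
        )
    return pd.concat(out, ignore_index=True)


def variance_by_size(table: pd.DataFrame) -> pd.DataFrame:
    """Replicate variance of pi per (species, m) — the plot data behind the
    cutoff choice."""
    return (
        table.groupby(["species_id", "m"])["pi"]
        .var(ddof=1)
        .rename("variance")
        .reset_index()
    )


def median_diversity(
    alignments: Mapping[str, AlignedSeqSet],
    reps: int = 100,
    seed: int = 0,
    replicate_size: Literal["own_n", "fixed"] = "own_n",
    fixed_m: int = 4,
    deletion_mode: str = "complete",
) -> pd.Series:
    """Median pi across bootstrap replicates per species.

    Replicates draw each species' own n sequences with replacement by
    default; ``replicate_size='fixed'`` draws ``fixed_m`` instead.
    """
    ss = np.random.SeedSequence(seed)
    keys = sorted(alignments)
    med = {}
    for key, child in zip(keys, ss.spawn(len(keys))):
        aln = alignments[key]
        m = aln.n if replicate_size == "own_n" else fixed_m
        tab = resample_diversity(aln, [m], reps, np.random.default_rng(child), deletion_mode)
        med[key] = float(tab["pi"].median())
    return pd.Series(med, name="median_pi")


def cutoff_rerun(
    species: pd.DataFrame,
    alignments: Mapping[str, AlignedSeqSet],
    cutoff: int = 4,
    reps: int = 100,
    seed: int = 0,
    replicate_size: Literal["own_n", "fixed"] = "own_n",
    zero_mode: str = "sv_zeros",
) -> tuple[DesignMatrix, BetaRegressionResults, int]:
    """Re-run the regression on species with at least ``cutoff`` sequences,
    using median resampled diversity as the response.

    Returns the rerun design, the fixed+precision fit and the retained
    species count.  The caller can re-apply spatial filtering / bootstrap to
    the returned design exactly as for the primary fit.
    """
    keep = species["n_sequences"] >= cutoff
    retained = int(keep.sum())
    n_cov = 7  # intercept + 6 fixed effects
    if retained < n_cov + 2:
        raise ValueError(
            f"only {retained} species have n >= {cutoff}; too few to refit"
        )
    sub = species.loc[keep].reset_index(drop=True)
    med = median_diversity(
        {k: alignments[k] for k in sub["species_id"]},
        reps=reps,
        seed=seed,
        replicate_size=replicate_size,
        fixed_m=cutoff,
    )
    sub = sub.assign(median_pi=med.loc[sub["species_id"]].to_numpy())
    design = assemble_design(sub, zero_mode=zero_mode, response_column="median_pi")
    fit = BetaRegression.from_design(design).fit()
    return design, fit, retained
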