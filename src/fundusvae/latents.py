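"""Image-derived features (IDFs): extraction, concatenation, export.

Latent phenotypes are the posterior means mu — deterministic functions of
the input image, which is what downstream genetic association needs. Rows
are indexed by (subject_id, eye); columns carry a stream prefix so the three
streams can be concatenated without collisions.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "extract_latents",
    "concat_streams",
    "standardize",
    "export_pheno",
    "read_pheno",
]


class AlignmentError(ValueError):
    pass


def _key_index(keys: Sequence[tuple[str, str]]) -> pd.MultiIndex:
    return pd.MultiIndex.from_tuples(list(keys), names=["subject_id", "eye"])


def extract_latents(results, x: np.ndarray, keys: Sequence[tuple[str, str]]) -> pd.DataFrame:
    """Per-sample posterior means as a DataFrame, one column per latent dim.

    ``results`` is a fitted :class:`~fundusvae.train.StreamVAEResults` (or any
    object with ``encode_mu`` and ``config``).
    """
    if len(x) != len(keys):
        raise AlignmentError(f"{len(x)} inputs but {len(keys)} sample keys")
    mu = results.encode_mu(np.asarray(x, dtype=np.float32))
    stream = results.config.stream
    cols = [f"{stream}_z{i}" for i in range(mu.shape[1])]
    return pd.DataFrame(mu, index=_key_index(keys), columns=cols)


def concat_streams(
    background: pd.DataFrame, disc_cup: pd.DataFrame, vessel: pd.DataFrame
) -> pd.DataFrame:
    """Row-align the three streams by (subject_id, eye) and concatenate columns."""
    frames = {"background": background, "disc_cup": disc_cup, "vessel": vessel}
    keys0 = set(background.index)
    for name, f in frames.items():
        diff = keys0.symmetric_difference(set(f.index))
        if diff:
            offenders = sorted(diff)[:10]
            raise AlignmentError(f"row keys differ between streams ({name}): {offenders}")
    ordered = [f.loc[background.index] for f in frames.values()]
    out = pd.concat(ordered, axis=1)
    if out.columns.duplicated().any():
        raise AlignmentError("duplicate column names after concatenation")
    return out


def standardize(latents: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Column-wise z-scoring (population sd, ddof=0).

    Returns the standardized matrix and a (mean, sd, constant) table;
    constant columns are flagged and mapped to zero.
    """
    if len(latents) < 2:
        raise ValueError("standardize requires at least 2 rows")
    mean = latents.mean(axis=0)
    sd = latents.std(axis=0, ddof=0)
    constant = sd <= 0
    safe_sd = sd.where(~constant, 1.0)
    z = (latents - mean) / safe_sd
    z.loc[:, constant] = 0.0
    stats = pd.DataFrame({"mean": mean, "sd": sd, "constant": constant})
    return z, stats


def export_pheno(latents: pd.DataFrame, path) -> None:
    """Write a GWAS-style phenotype file: FID IID then one column per latent."""
    df = latents.copy()
    if df.isna().any().any():
        raise ValueError("latent matrix contains missing values")
    sid = df.index.get_level_values("subject_id")
    eye = df.index.get_level_values("eye")
    out = pd.DataFrame({"FID": sid, "IID": [f"{s}_{e}" for s, e in zip(sid, eye)]})
    out = pd.concat([out.reset_index(drop=True), df.reset_index(drop=True)], axis=1)
    out.to_csv(path, sep=" ", index=False, float_format="%.8g")


def read_pheno(path) -> pd.DataFrame:
    """Parse a phenotype file written by :func:`export_pheno`."""
    df = pd.read_csv(path, sep=r"\s+")
    sid = df["FID"].astype(str)
    eye = df["IID"].str.rsplit("_", n=1).str[-1]
    df = df.drop(columns=["FID", "IID"])
    df.index = pd.MultiIndex.from_arrays([sid, eye], names=["subject_id", "eye"])
    return df
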