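"""Probe-level quality filtering, beta/M conversion and promoter annotation.

Methylation matrices are plain :class:`pandas.DataFrame` objects with probe
identifiers as the index and sample identifiers as columns.  Beta values are
fractions methylated in [0, 1]; M-values are their logit2 transform, the scale
conventionally used for linear-model testing on methylation arrays.

Probe annotation is a DataFrame indexed by ``probe_id`` with columns
``chromosome``, ``position`` (1-based), ``snp_flag``, ``multimap_flag`` and a
``detection_p`` column holding the per-probe maximum detection p-value across
samples (or a full probe x sample detection matrix passed separately).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "filter_probes",
    "beta_to_m",
    "m_to_beta",
    "annotate_promoters",
    "read_beta_tsv",
    "write_beta_tsv",
    "read_gene_models",
]

#: chromosome names treated as sex chromosomes (case-insensitive match)
SEX_CHROMOSOMES = {"x", "y", "chrx", "chry"}


def _is_sex_chromosome(chrom: pd.Series) -> pd.Series:
    return chrom.astype(str).str.lower().isin(SEX_CHROMOSOMES)


def filter_probes(
    beta: pd.DataFrame,
    annotation: pd.DataFrame,
    detection_p: pd.DataFrame | None = None,
    detection_threshold: float = 0.01,
) -> pd.DataFrame:
    """Remove probes unsuitable for methylation analysis.

    A probe is dropped when any of the following holds:

    * it overlaps a known germline polymorphism (``snp_flag``),
    * it maps to multiple genomic loci (``multimap_flag``),
    * it lies on a sex chromosome (X/Y, ``chr`` prefix and case ignored),
    * its maximum detection p-value exceeds ``detection_threshold`` in at
      least one sample.

    Parameters
    ----------
    beta
        Probes x samples beta matrix.
    annotation
        Probe annotation indexed by probe id.  Must cover every probe in
        ``beta``.  May carry a ``detection_p`` column with the per-probe
        maximum detection p-value.
    detection_p
        Optional probe x sample detection p-value matrix; takes precedence
        over the annotation column when given.
    detection_threshold
        Detection p-value cutoff (default 0.01); a probe failing in a single
        sample is removed.

    Returns
    -------
    pandas.DataFrame
        The beta matrix restricted to surviving probes, original order kept.
    """
    missing = beta.index.difference(annotation.index)
    if len(missing) > 0:
        raise KeyError(
            "probes missing from annotation: " + ", ".join(map(str, missing[:10]))
            + ("..." if len(missing) > 10 else "")
        )
    annot = annotation.loc[beta.index]

    bad = pd.Series(False, index=beta.index)
    if "snp_flag" in annot:
        bad |= annot["snp_flag"].astype(bool)
    if "multimap_flag" in annot:
        bad |= annot["multimap_flag"].astype(bool)
    if "chromosome" in annot:
        bad |= _is_sex_chromosome(annot["chromosome"])

    if detection_p is not None:
        max_p = detection_p.reindex(beta.index).max(axis=1)
    elif "detection_p" in annot:
        max_p = annot["detection_p"].astype(float)
    else:
        max_p = pd.Series(0.0, index=beta.index)
    bad |= max_p > detection_threshold

    return beta.loc[~bad]


def beta_to_m(beta, clamp: float = 1e-6):
    """Logit2 transform: ``M = log2(beta / (1 - beta))``.

    Beta values are symmetrically clamped to ``[clamp, 1 - clamp]`` first so
    the result is finite everywhere.  The map is strictly increasing and
    antisymmetric about beta = 0.5 (M(0.5) = 0).  Accepts and returns either
    a DataFrame or an ndarray.
    """
    if not 0 < clamp < 0.5:
        raise ValueError("clamp must be in (0, 0.5)")
    b = np.clip(np.asarray(beta, dtype=float), clamp, 1.0 - clamp)
    m = np.log2(b / (1.0 - b))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(m, index=beta.index, columns=beta.columns)
    return m


def m_to_beta(m):
    """Inverse of :func:`beta_to_m` (ignoring the clamp): ``beta = 2^M / (1 + 2^M)``."""
    x = np.power(2.0, np.asarray(m, dtype=float))
    b = x / (1.0 + x)
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(b, index=m.index, columns=m.columns)
    return b


def annotate_promoters(
    annotation: pd.DataFrame,
    genes: pd.DataFrame,
    upstream: int = 1500,
    downstream: int = 1000,
) -> pd.DataFrame:
    """Map probes to genes whose promoter window contains the probe position.

    The promoter is the closed interval from ``upstream`` bp upstream to
    ``downstream`` bp downstream of the TSS, in transcription direction:
    ``[tss - upstream, tss + downstream]`` for + strand genes and
    ``[tss - downstream, tss + upstream]`` for - strand genes.  Coordinates
    are 1-based inclusive on both sides.  A probe may map to several genes.

    Parameters
    ----------
    annotation
        Probe annotation with ``chromosome`` and ``position`` columns,
        indexed by probe id.
    genes
        Gene models with ``gene_id``, ``chromosome``, ``tss`` and ``strand``
        columns (strand in {+, -}).

    Returns
    -------
    pandas.DataFrame
        Two columns, ``probe_id`` and ``gene_id``, one row per mapping,
        sorted by (probe_id, gene_id) for determinism.
    """
    strands = set(genes["strand"].astype(str))
    unknown = strands - {"+", "-"}
    if unknown:
        raise ValueError(f"unknown strand symbol(s): {sorted(unknown)}")

    rows: list[tuple] = []
    probe_chrom = annotation["chromosome"].astype(str)
    probe_pos = annotation["position"].astype(int)
    for chrom, gsub in genes.groupby(genes["chromosome"].astype(str)):
        mask = probe_chrom == chrom
        if not mask.any():
            continue
        pos = probe_pos[mask]
        ids = pos.index
        tss = gsub["tss"].to_numpy(dtype=int)
        plus = (gsub["strand"] == "+").to_numpy()
        lo = np.where(plus, tss - upstream, tss - downstream)
        hi = np.where(plus, tss + downstream, tss + upstream)
        gid = gsub["gene_id"].to_numpy()
        p = pos.to_numpy()[:, None]
        hit = (p >= lo[None, :]) & (p <= hi[None, :])
        pi, gi = np.nonzero(hit)
        rows.extend(zip(ids[pi], gid[gi]))

    out = pd.DataFrame(rows, columns=["probe_id", "gene_id"])
    return out.sort_values(["probe_id", "gene_id"], ignore_index=True)


def read_beta_tsv(path) -> pd.DataFrame:
    """Read a probes x samples matrix from TSV (first column = probe id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df


def write_beta_tsv(beta: pd.DataFrame, path) -> None:
    beta.to_csv(path, sep="\t", index_label="probe_id")


def read_gene_models(path) -> pd.DataFrame:
    """Read gene models from a minimal TSV: gene_id, chromosome, tss, strand."""
    genes = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chromosome", "tss", "strand"}
    missing = required - set(genes.columns)
    if missing:
        raise ValueError(f"gene model table missing columns: {sorted(missing)}")
    return genes
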