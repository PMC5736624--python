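"""Synthetic cohorts with the structure the stratification analysis assumes.

The generator emulates a methylation-array study of a small leukemia
cohort: three latent clusters of samples with ordered mean methylation
(low / intermediate / high) at a set of signature probes, a background of
uninformative probes, a healthy-control group resembling the low cluster,
cluster-dependent 4-year event rates and clinical covariates, and paired
count-based (bisulfite-sequencing-style) methylomes for the pilot
concordance analysis.  Everything downstream of raw-intensity processing
can therefore be exercised without any external data.

All randomness flows from a single seed; per-component sub-streams are
derived deterministically, so identical configuration gives bit-identical
output.  Probe archetypes and annotation come from a separate
``structure_seed`` so that discovery and validation cohorts drawn with
different sample seeds share the same probe space.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "SimulatedCohort",
    "generate_cohort",
    "generate_outcomes",
    "generate_errbs_pair",
    "generate_gene_models",
    "generate_expression",
    "write_cohort",
]

CLUSTER_NAMES = ("low", "intermediate", "high")

# sub-stream ids (mixed into the seed sequence per component)
_STREAM_STRUCTURE = 0
_STREAM_BETA = 1
_STREAM_OUTCOME = 2
_STREAM_COVARIATE = 3
_STREAM_CONTROL = 4


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one simulated cohort.

    Parameters
    ----------
    n_probes
        Total probes on the simulated array (signature + background).
    n_signature_probes
        Probes carrying the cluster structure.
    cluster_sizes
        Patients per cluster, low to high (discovery default 15/11/13).
    cluster_mean_beta
        Strictly increasing mean beta per cluster at signature probes.
    background_beta_mean, background_beta_sd
        All background probes share one mean with small dispersion, so they
        never pass the variability selection.
    noise_sd
        Within-cluster beta SD at signature probes.
    archetype_jitter_sd
        Per-probe shift applied to all three cluster means jointly, giving
        probes individual archetypes without disturbing the ordering.
    event_rates
        Per-cluster 4-year event fractions (defaults 1/15, 5/11, 8/13).
    control_n
        Healthy controls, drawn from the low-cluster archetype with halved
        noise so they sit adjacent to (slightly tighter than) that cluster.
    seed
        Sample-level RNG seed; distinct cohorts use distinct seeds.
    structure_seed
        Probe-level RNG seed; cohorts sharing it share probes/archetypes.
    """

    n_probes: int = 20_000
    n_signature_probes: int = 1527
    cluster_sizes: tuple = (15, 11, 13)
    cluster_mean_beta: tuple = (0.2, 0.5, 0.8)
    background_beta_mean: float = 0.5
    background_beta_sd: float = 0.05
    noise_sd: float = 0.10
    archetype_jitter_sd: float = 0.05
    event_rates: tuple = (1 / 15, 5 / 11, 8 / 13)
    control_n: int = 22
    seed: int = 0
    structure_seed: int = 20170
    cohort_name: str = "discovery"
    sample_prefix: str = "S"

    def validate(self) -> None:
        if self.n_probes < self.n_signature_probes or self.n_signature_probes < 1:
            raise ValueError("n_probes must be >= n_signature_probes >= 1")
        if len(self.cluster_sizes) != len(self.cluster_mean_beta):
            raise ValueError("cluster_sizes and cluster_mean_beta lengths differ")
        if any(s < 1 for s in self.cluster_sizes):
            raise ValueError("cluster_sizes must all be >= 1")
        diffs = np.diff(self.cluster_mean_beta)
        if not np.all(diffs > 0):
            raise ValueError("cluster_mean_beta must be strictly increasing")
        for name in ("cluster_mean_beta", "background_beta_mean"):
            vals = np.atleast_1d(getattr(self, name))
            if np.any(vals <= 0) or np.any(vals >= 1):
                raise ValueError(f"{name} values must lie in (0, 1)")
        if len(self.event_rates) != len(self.cluster_sizes):
            raise ValueError("event_rates must match cluster_sizes")
        if any(not 0 <= r <= 1 for r in self.event_rates):
            raise ValueError("event_rates must lie in [0, 1]")
        for name in ("background_beta_sd", "noise_sd", "archetype_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.control_n < 0:
            raise ValueError("control_n must be non-negative")

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


@dataclass
class SimulatedCohort:
    """A generated cohort: beta matrix, annotation, sample table, archetypes."""

    beta: pd.DataFrame
    annotation: pd.DataFrame
    samples: pd.DataFrame
    archetypes: pd.DataFrame
    config: SimConfig

    @property
    def patient_ids(self) -> pd.Index:
        return self.samples.index[self.samples["true_cluster"] != "control"]

    @property
    def patient_beta(self) -> pd.DataFrame:
        return self.beta[self.patient_ids]


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


def _beta_draw(rng, mean, sd, size):
    """Beta-distributed draws reparameterized by (mean, sd), clamped.

    ``sd = 0`` returns the mean exactly.  Requires ``sd^2 < mean (1-mean)``
    so the Beta shape parameters are positive; results are clamped to
    [1e-6, 1 - 1e-6] to respect the open support.
    """
    mean = np.broadcast_to(np.asarray(mean, dtype=float), size)
    if sd == 0:
        return mean.copy()
    var = sd * sd
    cap = mean * (1.0 - mean)
    if np.any(var >= cap):
        raise ValueError("noise sd too large for a Beta draw at this mean")
    nu = cap / var - 1.0
    a, b = mean * nu, (1.0 - mean) * nu
    return np.clip(rng.beta(a, b), 1e-6, 1.0 - 1e-6)


def _structure(config: SimConfig):
    """Probe ids, annotation and signature archetypes (structure stream)."""
    rng = _rng(config.structure_seed, _STREAM_STRUCTURE)
    n, n_sig = config.n_probes, config.n_signature_probes
    probe_ids = [f"cg{i:08d}" for i in range(n)]
    signature = probe_ids[:n_sig]

    # per-probe shift common to all clusters keeps the low<mid<high ordering
    jitter = rng.normal(0.0, config.archetype_jitter_sd, size=n_sig)
    means = np.asarray(config.cluster_mean_beta, dtype=float)
    arch = np.clip(means[None, :] + jitter[:, None], 0.05, 0.95)
    archetypes = pd.DataFrame(
        arch, index=signature, columns=list(CLUSTER_NAMES[: len(means)])
    )

    # annotation: signature probes always pass filtering; a slice of the
    # background carries sex-chromosome / SNP / multi-map / detection flags
    chrom = rng.integers(1, 23, size=n).astype(str)
    position = rng.integers(1, 2_000_000_00, size=n)
    snp = np.zeros(n, dtype=bool)
    multi = np.zeros(n, dtype=bool)
    det = rng.uniform(0.0, 0.005, size=n)
    bg = np.arange(n_sig, n)
    if len(bg) > 0:
        sex_pick = rng.choice(bg, size=max(1, int(0.02 * len(bg))), replace=False)
        chrom[sex_pick] = rng.choice(["X", "Y", "chrX", "chrY"], size=len(sex_pick))
        snp[rng.choice(bg, size=max(1, int(0.01 * len(bg))), replace=False)] = True
        multi[rng.choice(bg, size=max(1, int(0.01 * len(bg))), replace=False)] = True
        det[rng.choice(bg, size=max(1, int(0.005 * len(bg))), replace=False)] = 0.02
    annotation = pd.DataFrame(
        {
            "chromosome": chrom,
            "position": position,
            "snp_flag": snp,
            "multimap_flag": multi,
            "detection_p": det,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    return probe_ids, signature, archetypes, annotation


def generate_outcomes(labels, rates, mode: str = "exact", seed=None):
    """Draw per-sample binary 4-year event indicators from per-cluster rates.

    ``mode="exact"`` allocates exactly ``round(rate * n_cluster)`` events
    per cluster at random positions; ``mode="bernoulli"`` draws each sample
    independently.  ``rates`` maps each label to its event fraction.
    """
    labels = pd.Series(labels)
    rates = dict(rates)
    missing = set(labels.unique()) - set(rates)
    if missing:
        raise ValueError(f"no event rate for label(s): {sorted(missing)}")
    for lab, r in rates.items():
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"event rate for {lab!r} outside [0, 1]: {r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    events = pd.Series(0, index=labels.index, dtype=int)
    for lab in sorted(map(str, labels.unique())):
        members = labels.index[labels.astype(str) == lab]
        r = rates[[k for k in rates if str(k) == lab][0]]
        if mode == "exact":
            k = int(round(r * len(members)))
            hit = rng.choice(len(members), size=k, replace=False)
            events.loc[members[hit]] = 1
        elif mode == "bernoulli":
            events.loc[members] = (rng.random(len(members)) < r).astype(int)
        else:
            raise ValueError("mode must be 'exact' or 'bernoulli'")
    return events


def _covariates(labels: pd.Series, rng: np.random.Generator) -> pd.DataFrame:
    """Cluster-dependent clinical covariates.

    Probabilities rise with methylation so univariable associations exist
    without being deterministic: older age, elevated fetal hemoglobin and
    >1 somatic mutation are all more frequent in the higher clusters;
    tissue source is independent of cluster; spontaneous resolution is
    essentially a low-cluster phenomenon.
    """
    idx = {"low": 0, "intermediate": 1, "high": 2, "control": 0}
    ci = labels.map(idx).to_numpy()
    n = len(labels)
    age_median = np.array([12.0, 24.0, 36.0])[ci]
    age = np.round(age_median * np.exp(rng.normal(0.0, 0.6, n)), 1)
    hbf = (rng.random(n) < np.array([0.25, 0.55, 0.75])[ci]).astype(int)
    muts = rng.poisson(np.array([0.7, 1.3, 1.9])[ci])
    tissue = rng.choice(
        ["bone_marrow", "peripheral_blood", "spleen"], size=n, p=[0.34, 0.49, 0.17]
    )
    platelet = (rng.random(n) < 0.5).astype(int)
    ptpn11 = (rng.random(n) < 0.33).astype(int)
    gender = rng.choice(["male", "female"], size=n, p=[0.7, 0.3])
    sr = (rng.random(n) < np.array([0.6, 0.05, 0.0])[ci]).astype(int)
    return pd.DataFrame(
        {
            "age_months": age,
            "hbf_elevated": hbf,
            "n_somatic_mutations": muts,
            "tissue_source": tissue,
            "platelet_gt50": platelet,
            "ptpn11": ptpn11,
            "gender": gender,
            "spontaneous_resolution": sr,
        },
        index=labels.index,
    )


def generate_cohort(config: SimConfig) -> SimulatedCohort:
    """Generate a full simulated cohort (patients plus healthy controls).

    Signature probes get cluster-specific Beta-distributed values around
    per-probe archetypes; background probes share one mean with small
    dispersion; controls are drawn from the low-cluster archetype with
    halved noise.  Outcomes use exact per-cluster allocation of the
    configured event rates; covariates are cluster-dependent.  Identical
    config (including seed) gives bit-identical output.
    """
    config.validate()
    probe_ids, signature, archetypes, annotation = _structure(config)
    k = len(config.cluster_sizes)
    names = CLUSTER_NAMES[:k]

    pat_ids = [
        f"{config.sample_prefix}{i + 1:02d}" for i in range(sum(config.cluster_sizes))
    ]
    ctl_ids = [f"{config.sample_prefix}C{i + 1:02d}" for i in range(config.control_n)]
    labels = pd.Series(
        np.repeat(list(names), list(config.cluster_sizes)),
        index=pd.Index(pat_ids, name="sample_id"),
    )

    rng_beta = _rng(config.seed, _STREAM_BETA)
    n_sig, n_bg = config.n_signature_probes, config.n_probes - config.n_signature_probes
    cols = {}
    for sid in pat_ids:
        arch = archetypes[labels[sid]].to_numpy()
        sig = _beta_draw(rng_beta, arch, config.noise_sd, (n_sig,))
        bg = _beta_draw(
            rng_beta, config.background_beta_mean, config.background_beta_sd, (n_bg,)
        )
        cols[sid] = np.concatenate([sig, bg])
    rng_ctl = _rng(config.seed, _STREAM_CONTROL)
    for sid in ctl_ids:
        arch = archetypes["low"].to_numpy()
        sig = _beta_draw(rng_ctl, arch, config.noise_sd / 2.0, (n_sig,))
        bg = _beta_draw(
            rng_ctl, config.background_beta_mean, config.background_beta_sd, (n_bg,)
        )
        cols[sid] = np.concatenate([sig, bg])
    beta = pd.DataFrame(cols, index=pd.Index(probe_ids, name="probe_id"))

    rng_out = _rng(config.seed, _STREAM_OUTCOME)
    rates = dict(zip(names, config.event_rates))
    events = generate_outcomes(labels, rates, mode="exact", seed=rng_out)

    rng_cov = _rng(config.seed, _STREAM_COVARIATE)
    all_labels = pd.concat(
        [labels, pd.Series("control", index=pd.Index(ctl_ids, name="sample_id"))]
    )
    covs = _covariates(all_labels, rng_cov)

    followup = pd.Series(48.0, index=all_labels.index)
    ev_ids = events.index[events == 1]
    followup.loc[ev_ids] = np.round(rng_cov.uniform(2.0, 47.9, len(ev_ids)), 1)

    samples = pd.DataFrame(
        {
            "cohort": [config.cohort_name] * len(pat_ids) + ["control"] * len(ctl_ids),
            "true_cluster": all_labels,
            "event_4yr": events.reindex(all_labels.index),
            "followup_months": followup,
        }
    ).join(covs)
    samples.loc[ctl_ids, ["spontaneous_resolution"]] = 0

    return SimulatedCohort(
        beta=beta,
        annotation=annotation,
        samples=samples,
        archetypes=archetypes,
        config=config,
    )


def generate_errbs_pair(
    n_sites: int,
    coverage_mean: float,
    concordance: float,
    seed=None,
):
    """Paired count-based methylomes with a target concordance.

    Each site carries a latent methylation fraction drawn from a bimodal
    Beta(0.3, 0.3) (the shape of genome-wide CpG methylation).  Both
    members observe the shared latent fraction through independent
    perturbations sized so that, together with binomial sampling noise at
    the given mean coverage, the expected concordance correlation
    coefficient of the observed fractions matches ``concordance``.
    ``concordance <= 0`` draws the two latent fractions independently.
    Coverage is 1 + Poisson(coverage_mean - 1) per site and member.

    Returns two call tables in the layout of
    :func:`methstrat.errbs.read_coverage_file`.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if coverage_mean < 1:
        raise ValueError("coverage_mean must be >= 1")
    if concordance > 1:
        raise ValueError("concordance must be <= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    a_shape = b_shape = 0.3
    var_latent = (a_shape * b_shape) / (
        (a_shape + b_shape) ** 2 * (a_shape + b_shape + 1)
    )
    mean_pq = (a_shape * b_shape) / ((a_shape + b_shape) * (a_shape + b_shape + 1))
    lam = coverage_mean - 1.0
    inv_cov = 1.0 if lam <= 0 else (1.0 - np.exp(-lam)) / lam
    eps2 = mean_pq * inv_cov  # expected binomial noise variance per member

    positions = np.cumsum(rng.integers(2, 200, size=n_sites))
    latent = rng.beta(a_shape, b_shape, size=n_sites)

    def observe(latent_member):
        cov = 1 + rng.poisson(lam, size=n_sites)
        meth = rng.binomial(cov, latent_member)
        return pd.DataFrame(
            {
                "chromosome": "1",
                "position": positions,
                "meth_count": meth,
                "total_count": cov,
                "percent": 100.0 * meth / cov,
            }
        )

    if concordance <= 0:
        lat_a = latent
        lat_b = rng.beta(a_shape, b_shape, size=n_sites)
    else:
        tau2 = max(0.0, var_latent * (1.0 / concordance - 1.0) - eps2)
        tau = np.sqrt(tau2)

        def perturb():
            x = latent + rng.normal(0.0, tau, size=n_sites)
            # reflect into [0,1]; preserves perturbation variance near edges
            x = np.abs(x)
            x = 1.0 - np.abs(1.0 - x)
            return np.clip(x, 0.0, 1.0)

        lat_a = perturb() if tau > 0 else latent
        lat_b = perturb() if tau > 0 else latent
    return observe(lat_a), observe(lat_b)


def generate_gene_models(
    annotation: pd.DataFrame,
    n_genes: int = 400,
    seed: int = 0,
) -> pd.DataFrame:
    """Gene models whose promoters cover a subset of the probes.

    Each gene's TSS is placed near a randomly chosen probe so that the
    promoter window (1.5 kb upstream / 1 kb downstream) contains it;
    strands alternate.  Deterministic for a given annotation and seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7]))
    pick = rng.choice(len(annotation), size=min(n_genes, len(annotation)),
                      replace=False)
    rows = []
    for g, i in enumerate(sorted(pick)):
        probe = annotation.iloc[i]
        strand = "+" if g % 2 == 0 else "-"
        offset = int(rng.integers(-900, 900))
        rows.append(
            {
                "gene_id": f"GENE{g:04d}",
                "chromosome": str(probe["chromosome"]),
                "tss": max(1, int(probe["position"]) + offset),
                "strand": strand,
            }
        )
    return pd.DataFrame(rows)


def generate_expression(
    samples: pd.DataFrame,
    gene_ids,
    de_genes=None,
    effect: float = 3.0,
    seed: int = 0,
) -> pd.DataFrame:
    """log2(TPM + 1) expression for the given samples.

    Genes in ``de_genes`` get a mean shift of ``effect`` log2 units in
    samples with an event; all genes carry lognormal baseline levels and
    normal noise, floored at zero (values are log2 of TPM + 1, hence
    non-negative).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))
    gene_ids = list(gene_ids)
    de = set(de_genes or [])
    base = rng.uniform(1.0, 8.0, size=len(gene_ids))
    mat = base[:, None] + rng.normal(0.0, 1.0, size=(len(gene_ids), len(samples)))
    ev = samples["event_4yr"].fillna(0).to_numpy(dtype=float)
    for i, g in enumerate(gene_ids):
        if g in de:
            mat[i] += effect * ev
    return pd.DataFrame(
        np.maximum(mat, 0.0), index=pd.Index(gene_ids, name="gene_id"),
        columns=samples.index,
    )


def write_cohort(cohort: SimulatedCohort, outdir) -> dict:
    """Write beta, annotation and sample tables as TSV; returns the paths."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "beta": os.path.join(outdir, f"beta_{cohort.config.cohort_name}.tsv"),
        "annotation": os.path.join(outdir, "annotation.tsv"),
        "samples": os.path.join(outdir, f"samples_{cohort.config.cohort_name}.tsv"),
    }
    cohort.beta.to_csv(paths["beta"], sep="\t")
    cohort.annotation.to_csv(paths["annotation"], sep="\t")
    cohort.samples.to_csv(paths["samples"], sep="\t", index_label="sample_id")
    return paths
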