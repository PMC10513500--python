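"""Synthetic multi-omics generator with known subgroup structure.

Emulates the statistical shape of a 450K-style medulloblastoma cohort:
a probes x samples beta matrix with subgroup-specific hypo/hyper-methylated
probe blocks, a coupled gene-expression view, class imbalance (default
minority class WNT = 70 of 763), paired methylated/unmethylated intensity
matrices with detection p-values, and subgroup-dependent right-censored
survival.  Every generator is a pure function of its spec and seed.

Betas are drawn on the logit scale and inverse-transformed, which keeps
values in [0, 1] and reproduces the bimodality of real Illumina betas.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, logit

__all__ = [
    "SyntheticSpec",
    "LabeledOmics",
    "generate_omics",
    "generate_intensities",
    "generate_survival",
    "write_dataset",
]

#: default cohort composition: only the minority size (WNT = 70) and the
#: total (763) mirror the reference cohort; the remaining split is an
#: arbitrary, documented choice.
DEFAULT_CLASS_COUNTS = {"WNT": 70, "SHH": 200, "Group3": 150, "Group4": 343}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic multi-omics draw.

    Parameters
    ----------
    class_counts
        Subgroup name -> number of samples.
    n_probes
        Total CpG probes in the beta matrix.
    n_informative
        Number of probes carrying subgroup signal; the rest are
        label-independent noise.
    delta
        Mean beta separation between hypo- and hyper-methylated groups on
        informative probes (0-1).
    noise_sd
        Gaussian noise SD added on the logit scale.
    n_genes
        Genes in the expression view (half carry the shared latent block
        signal, half are noise).
    coupling
        Correlation strength in [0, 1] between the views' shared signal.
    censor_rate
        Expected fraction of censored survival records, in [0, 1).
    log_hr
        Subgroup -> log hazard ratio relative to the baseline rate.
    seed
        Root seed; identical spec + seed gives bit-identical output.
    """

    class_counts: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_COUNTS)
    )
    n_probes: int = 1000
    n_informative: int = 100
    delta: float = 0.4
    noise_sd: float = 0.05
    n_genes: int = 200
    coupling: float = 0.8
    censor_rate: float = 0.3
    log_hr: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.class_counts:
            raise ValueError("class_counts must be non-empty")
        for name, count in self.class_counts.items():
            if count <= 0:
                raise ValueError(f"class count for {name!r} must be > 0")
        for name, value in [("n_probes", self.n_probes), ("n_genes", self.n_genes),
                            ("n_informative", self.n_informative)]:
            if value <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_informative > self.n_probes:
            raise ValueError("n_informative cannot exceed n_probes")
        if not 0.0 < self.delta < 1.0:
            raise ValueError("delta must lie in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must lie in [0, 1]")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValueError("censor_rate must lie in [0, 1)")
        unknown = set(self.log_hr) - set(self.class_counts)
        if unknown:
            raise ValueError(f"log_hr refers to unknown subgroups: {sorted(unknown)}")

    @property
    def n_samples(self) -> int:
        return sum(self.class_counts.values())

    @property
    def groups(self) -> list[str]:
        return list(self.class_counts)


@dataclass
class LabeledOmics:
    """One synthetic cohort: beta view, expression view, and truth labels."""

    beta: pd.DataFrame  # probes x samples, values in [0, 1]
    expression: pd.DataFrame  # genes x samples
    labels: pd.Series  # subgroup per sample, indexed by sample id
    informative_probes: list[str]
    informative_genes: list[str]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.beta.columns)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.beta.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.expression.index)


def _group_patterns(n_probes: int, n_groups: int, rng: np.random.Generator) -> np.ndarray:
    """Random non-constant binary hyper/hypo pattern over groups per probe.

    Each informative probe is hypermethylated in a random proper subset of
    the groups, so in expectation any two groups differ on half of the
    informative probes.
    """
    patterns = rng.integers(0, 2, size=(n_probes, n_groups))
    # redraw constant rows (all-hypo / all-hyper carry no signal)
    constant = np.ptp(patterns, axis=1) == 0
    while constant.any():
        patterns[constant] = rng.integers(0, 2, size=(int(constant.sum()), n_groups))
        constant = np.ptp(patterns, axis=1) == 0
    return patterns


def generate_omics(spec: SyntheticSpec) -> LabeledOmics:
    """Draw a labeled beta matrix and a coupled expression view.

    The two views share a latent one-hot subgroup factor: informative
    probes get subgroup-specific beta means ``0.5 +/- delta/2`` (logit
    noise ``noise_sd`` on top), and the first half of the genes are a
    random linear map of the same factor mixed with standard normal noise
    at weight ``coupling``.
    """
    rng = np.random.default_rng(spec.seed)
    groups = spec.groups
    n = spec.n_samples

    labels = np.repeat(groups, [spec.class_counts[g] for g in groups])
    group_index = {g: i for i, g in enumerate(groups)}
    z = np.array([group_index[g] for g in labels])

    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    probe_ids = [f"cg{i + 1:06d}" for i in range(spec.n_probes)]
    gene_ids = [f"GENE{i + 1:04d}" for i in range(spec.n_genes)]

    # --- beta view -------------------------------------------------------
    hi, lo = 0.5 + spec.delta / 2.0, 0.5 - spec.delta / 2.0
    patterns = _group_patterns(spec.n_informative, len(groups), rng)
    info_means = np.where(patterns == 1, hi, lo)  # informative x groups
    mu_info = logit(info_means[:, z])  # informative x samples

    # noise probes: bimodal probe-level baselines, identical across groups
    n_noise = spec.n_probes - spec.n_informative
    modes = rng.choice([-2.0, 2.0], size=n_noise)
    baseline = rng.normal(modes, 0.8)[:, None]
    mu_noise = np.broadcast_to(baseline, (n_noise, n))

    mu = np.vstack([mu_info, mu_noise])
    beta_values = expit(mu + rng.normal(0.0, spec.noise_sd, size=mu.shape))
    beta_values = np.clip(beta_values, 0.0, 1.0)
    beta = pd.DataFrame(beta_values, index=probe_ids, columns=sample_ids)

    # --- expression view -------------------------------------------------
    n_info_genes = max(1, spec.n_genes // 2)
    onehot = np.eye(len(groups))[z]  # samples x groups
    loadings = rng.normal(size=(n_info_genes, len(groups)))
    signal = loadings @ onehot.T
    mix = np.sqrt(max(0.0, 1.0 - spec.coupling**2))
    expr_info = spec.coupling * signal + mix * rng.normal(size=signal.shape)
    expr_noise = rng.normal(size=(spec.n_genes - n_info_genes, n))
    expression = pd.DataFrame(
        np.vstack([expr_info, expr_noise]), index=gene_ids, columns=sample_ids
    )

    return LabeledOmics(
        beta=beta,
        expression=expression,
        labels=pd.Series(labels, index=sample_ids, name="subgroup"),
        informative_probes=probe_ids[: spec.n_informative],
        informative_genes=gene_ids[:n_info_genes],
    )


def generate_intensities(
    spec: SyntheticSpec,
    target_beta: pd.DataFrame,
    total_intensity: float = 10_000.0,
    fail_probe_frac: float = 0.0,
    fail_sample_frac: float = 0.5,
    offset: float = 100.0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Invert the beta formula: build (M, U, P) recovering ``target_beta``.

    M and U are chosen so that ``M / (M + U + offset)`` equals the target
    exactly; per-entry total intensity is jittered log-normally around
    ``total_intensity``.  Detection p-values are near zero except on a
    ``fail_probe_frac`` fraction of probes, where a ``fail_sample_frac``
    fraction of samples receives p > 0.05 (failing measurements).
    """
    b = target_beta.to_numpy(dtype=float)
    if (b < 0).any() or (b >= 1).any():
        raise ValueError("target_beta must lie in [0, 1): beta = 1 is unreachable "
                         "with a positive offset")
    if not 0.0 <= fail_probe_frac <= 1.0 or not 0.0 <= fail_sample_frac <= 1.0:
        raise ValueError("failure fractions must lie in [0, 1]")
    rng = np.random.default_rng(spec.seed + 1)

    total = total_intensity * rng.lognormal(0.0, 0.1, size=b.shape)
    m = b * (total + offset)
    u = total - m
    # where the jittered total cannot reach the target beta, fall back to
    # the exact U = 0 solution M = offset * b / (1 - b)
    short = u < 0
    m[short] = offset * b[short] / (1.0 - b[short])
    u[short] = 0.0

    p = rng.uniform(0.0, 0.01, size=b.shape)
    n_fail_probes = int(round(fail_probe_frac * b.shape[0]))
    if n_fail_probes > 0:
        probe_rows = rng.choice(b.shape[0], size=n_fail_probes, replace=False)
        for row in probe_rows:
            n_fail = max(1, int(round(fail_sample_frac * b.shape[1])))
            cols = rng.choice(b.shape[1], size=n_fail, replace=False)
            p[row, cols] = rng.uniform(0.0500001, 1.0, size=n_fail)

    idx, cols = target_beta.index, target_beta.columns
    return (
        pd.DataFrame(m, index=idx, columns=cols),
        pd.DataFrame(u, index=idx, columns=cols),
        pd.DataFrame(p, index=idx, columns=cols),
    )


def generate_survival(labels: pd.Series, spec: SyntheticSpec) -> pd.DataFrame:
    """Exponential event times with per-subgroup proportional hazards.

    Event time for a sample in subgroup g has rate
    ``base_rate * exp(log_hr[g])`` (base rate 0.1 / year); censoring times
    are independent exponentials calibrated so that roughly
    ``spec.censor_rate`` of records are censored.  Age (years) and sex are
    drawn to resemble a pediatric cohort.

    Returns a table with columns (sample_id, subgroup, age, sex, time, event).
    """
    if len(labels) == 0:
        raise ValueError("labels must be non-empty")
    rng = np.random.default_rng(spec.seed + 2)
    base_rate = 0.1

    loghr = np.array([float(spec.log_hr.get(g, 0.0)) for g in labels])
    rates = base_rate * np.exp(loghr)
    event_times = rng.exponential(1.0 / rates)

    if spec.censor_rate > 0:
        # P(censored) = rc / (rc + re) for independent exponentials
        mean_rate = rates.mean()
        rate_c = mean_rate * spec.censor_rate / (1.0 - spec.censor_rate)
        censor_times = rng.exponential(1.0 / rate_c, size=len(labels))
        observed = np.minimum(event_times, censor_times)
        event = (event_times <= censor_times).astype(int)
    else:
        observed = event_times
        event = np.ones(len(labels), dtype=int)

    observed = np.maximum(observed, 1e-6)
    age = np.clip(rng.normal(8.0, 4.0, size=len(labels)), 0.5, None)
    sex = rng.choice(["M", "F"], size=len(labels))
    return pd.DataFrame(
        {
            "sample_id": list(labels.index),
            "subgroup": list(labels.to_numpy()),
            "age": age,
            "sex": sex,
            "time": observed,
            "event": event,
        }
    )


def make_annotation(
    probe_ids: list[str],
    n_genes: int | None = None,
    frac_unannotated: float = 0.1,
    frac_sex_chrom: float = 0.05,
    frac_snp: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic 450K-style probe annotation (probe_id, chr, gene, snp_flag).

    Probes are mapped to a pool of gene symbols (several probes per gene,
    as on the real array); a fraction lack any gene annotation, sit on sex
    chromosomes, or overlap SNPs.
    """
    rng = np.random.default_rng(seed)
    n = len(probe_ids)
    if n_genes is None:
        n_genes = max(1, n // 3)
    genes = np.array([f"GENE{i + 1:04d}" for i in range(n_genes)])
    gene = rng.choice(genes, size=n)
    gene[rng.random(n) < frac_unannotated] = ""
    chroms = rng.choice([str(c) for c in range(1, 23)], size=n)
    sex_mask = rng.random(n) < frac_sex_chrom
    chroms[sex_mask] = rng.choice(["X", "Y"], size=int(sex_mask.sum()))
    snp_flag = rng.random(n) < frac_snp
    return pd.DataFrame(
        {"probe_id": probe_ids, "chr": chroms, "gene": gene, "snp_flag": snp_flag}
    )


def write_dataset(omics: LabeledOmics, survival: pd.DataFrame, out_dir: str | Path) -> dict[str, Path]:
    """Write the cohort as TSV matrices plus a metadata table.

    Matrices are probes/genes x samples with the header row holding sample
    ids; metadata columns are (sample_id, subgroup, age, sex, time, event).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "beta": out / "beta.tsv",
        "expression": out / "expression.tsv",
        "metadata": out / "metadata.tsv",
    }
    omics.beta.to_csv(paths["beta"], sep="\t")
    omics.expression.to_csv(paths["expression"], sep="\t")
    survival.to_csv(paths["metadata"], sep="\t", index=False)
    return paths
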