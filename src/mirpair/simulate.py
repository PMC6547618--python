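"""Synthetic data with planted ground truth for every pipeline stage.

The count generator emulates a matched tumor-normal sequencing cohort:
negative-binomial counts whose log-mean is a feature baseline plus a
per-patient factor shared exactly by that patient's tumor and normal sample,
plus the planted condition effect, with library-size offsets.  The sequence
generator plants canonical seed sites of declared types into otherwise
uniform-random 3'UTRs.  The repression generator produces site-level
responses linear in the four context features, and the survival generator
draws exponential event times with group-dependent hazards tied to a
simulated expression value.

All randomness in a call flows from a single ``numpy.random.default_rng``
seeded by one integer, so identical parameters give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .containers import PairedCountMatrix, PatientPair
from .targets import SITE_LENGTHS, SeedSite, reverse_complement

__all__ = [
    "SimCountParams",
    "SimTruth",
    "simulate_paired_counts",
    "simulate_sequence_universe",
    "simulate_repression_data",
    "simulate_site_features",
    "simulate_survival_cohort",
    "simulate_gene_sets",
]

_RNA = np.array(list("ACGU"))


@dataclass
class SimCountParams:
    """Conditions for the matched-pair count generator.

    Defaults mirror a 48-patient matched cohort profiled at ~2000 features
    after low-expression filtering, with 5% of features planted as
    differentially expressed.  ``mean_log_range`` is the span of baseline
    abundance in log2 units of relative expression weight; ``dispersion`` is
    the NB dispersion (variance = mu + dispersion * mu^2); ``patient_sd`` is
    the standard deviation of the per-patient natural-log factor shared by
    the patient's tumor and normal sample.
    """

    n_features: int = 2000
    n_pairs: int = 48
    frac_de: float = 0.05
    logfc_range: tuple[float, float] = (1.5, 3.0)
    mean_log_range: tuple[float, float] = (0.0, 8.0)
    dispersion: float = 0.1
    patient_sd: float = 0.3
    libsize_range: tuple[int, int] = (800_000, 1_200_000)
    seed: int = 0
    feature_prefix: str = "feat"

    def __post_init__(self) -> None:
        if int(self.n_features) != self.n_features or self.n_features < 1:
            raise ValueError("n_features must be a positive integer")
        if int(self.n_pairs) != self.n_pairs or self.n_pairs < 1:
            raise ValueError("n_pairs must be a positive integer")
        if not 0.0 <= self.frac_de <= 1.0:
            raise ValueError("frac_de must lie in [0, 1]")
        if self.logfc_range[0] > self.logfc_range[1] or self.logfc_range[0] < 0:
            raise ValueError("logfc_range must satisfy 0 <= min <= max")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if self.patient_sd < 0:
            raise ValueError("patient_sd must be non-negative")
        lo, hi = self.libsize_range
        if lo <= 0 or hi < lo:
            raise ValueError("libsize_range must be positive with min <= max")


@dataclass
class SimTruth:
    """Planted ground truth emitted alongside each synthetic dataset."""

    de_features: list[tuple[str, float]] = field(default_factory=list)
    planted_sites: list[tuple[str, str, int, str]] = field(default_factory=list)
    mlr_coefficients: Optional[tuple[float, float, float, float, float]] = None
    survival_hazard_ratio: Optional[float] = None

    @property
    def de_feature_ids(self) -> set[str]:
        return {fid for fid, lfc in self.de_features if lfc != 0.0}

    def de_directions(self) -> dict[str, str]:
        return {
            fid: ("up" if lfc > 0 else "down")
            for fid, lfc in self.de_features
            if lfc != 0.0
        }


def simulate_paired_counts(
    params: SimCountParams,
) -> tuple[PairedCountMatrix, SimTruth]:
    """Draw a matched tumor-normal NB count matrix with planted fold changes.

    For feature i in sample s (patient p, condition c in {0=normal, 1=tumor}):

        log mu = log(libsize_s * rho_i) + a_p + c * lfc_i * log(2)

    where rho is the relative abundance from the baseline draw, a_p ~
    N(0, patient_sd) is the shared patient factor and lfc_i is the planted
    signed log2 fold change (0 for non-DE features).  Counts are NB with
    variance mu + dispersion * mu^2 (Poisson when dispersion = 0).
    """
    rng = np.random.default_rng(params.seed)
    nf, npair = params.n_features, params.n_pairs

    width = max(4, len(str(nf)))
    feature_ids = [f"{params.feature_prefix}{i + 1:0{width}d}" for i in range(nf)]

    base_log2 = rng.uniform(*params.mean_log_range, size=nf)
    rho = 2.0 ** base_log2
    rho /= rho.sum()

    n_de = int(round(params.frac_de * nf))
    lfc = np.zeros(nf)
    de_idx = rng.choice(nf, size=n_de, replace=False)
    if n_de:
        magnitude = rng.uniform(*params.logfc_range, size=n_de)
        sign = rng.choice([-1.0, 1.0], size=n_de)
        lfc[de_idx] = sign * magnitude

    patient_factor = rng.normal(0.0, params.patient_sd, size=npair)
    libsizes = rng.integers(
        params.libsize_range[0], params.libsize_range[1] + 1, size=2 * npair
    )

    sample_ids: list[str] = []
    manifest: list[PatientPair] = []
    cols = np.empty((nf, 2 * npair))
    for p in range(npair):
        pid = f"P{p + 1:03d}"
        for j, cond in enumerate((1, 0)):  # tumor then normal
            s = 2 * p + j
            mu = libsizes[s] * rho * np.exp(patient_factor[p]) * 2.0 ** (cond * lfc)
            cols[:, s] = mu
        sample_ids += [f"{pid}T", f"{pid}N"]
        manifest.append(PatientPair(pid, f"{pid}T", f"{pid}N"))

    if params.dispersion > 0:
        size = 1.0 / params.dispersion
        counts = rng.negative_binomial(size, size / (size + cols))
    else:
        counts = rng.poisson(cols)

    pcm = PairedCountMatrix(
        pd.DataFrame(counts, index=feature_ids, columns=sample_ids), manifest
    )
    truth = SimTruth(de_features=list(zip(feature_ids, lfc.tolist())))
    return pcm, truth


def _draw_sites_per_utr(
    dist: int | Mapping[int, float], rng: np.random.Generator, n: int
) -> np.ndarray:
    if isinstance(dist, int):
        return np.full(n, dist)
    ks = np.array(sorted(dist))
    ps = np.array([dist[k] for k in ks], dtype=float)
    ps /= ps.sum()
    return rng.choice(ks, size=n, p=ps)


def simulate_sequence_universe(
    n_mirnas: int,
    n_utrs: int,
    utr_len_range: tuple[int, int] = (200, 2000),
    sites_per_utr: int | Mapping[int, float] = 1,
    seed: int = 0,
    mirna_ids: Optional[Sequence[str]] = None,
    utr_ids: Optional[Sequence[str]] = None,
) -> tuple[dict[str, str], dict[str, str], SimTruth]:
    """Random miRNA and 3'UTR sequences with planted seed sites.

    miRNAs are 20-23 nt over {A,C,G,U}; UTR background is uniform-random.
    Each planted site is written as the exact pattern its declared type
    demands (8mer / 7mer-m8 / 7mer-A1), at a position recorded in the truth;
    flanking bases are adjusted where needed so a planted 7mer is not
    accidentally promoted to an 8mer, and planted spans never overlap.
    """
    if utr_len_range[0] < 30:
        raise ValueError("UTRs must be at least 30 nt so flanking windows exist")
    rng = np.random.default_rng(seed)

    if mirna_ids is None:
        mirna_ids = [f"mir-{i + 1:03d}" for i in range(n_mirnas)]
    if utr_ids is None:
        utr_ids = [f"gene-{i + 1:04d}" for i in range(n_utrs)]
    if len(mirna_ids) != n_mirnas or len(utr_ids) != n_utrs:
        raise ValueError("id list lengths must match n_mirnas / n_utrs")

    mirnas = {
        mid: "".join(rng.choice(_RNA, size=rng.integers(20, 24)))
        for mid in mirna_ids
    }

    site_types = np.array(["8mer", "7mer-m8", "7mer-A1"])
    n_sites = _draw_sites_per_utr(sites_per_utr, rng, n_utrs)
    utrs: dict[str, str] = {}
    planted: list[tuple[str, str, int, str]] = []
    for uid, k in zip(utr_ids, n_sites):
        length = int(rng.integers(utr_len_range[0], utr_len_range[1] + 1))
        seq = rng.choice(_RNA, size=length)
        taken: list[tuple[int, int]] = []  # planted spans incl. 1-nt margins
        for _ in range(int(k)):
            mid = mirna_ids[int(rng.integers(len(mirna_ids)))]
            stype = str(rng.choice(site_types))
            slen = SITE_LENGTHS[stype]
            pattern = _site_pattern(mirnas[mid], stype)
            for _attempt in range(50):
                start = int(rng.integers(0, length - slen + 1))
                lo, hi = start - 1, start + slen + 1
                if all(hi <= a or lo >= b for a, b in taken):
                    break
            else:
                continue  # UTR too crowded; plant fewer sites here
            seq[start : start + slen] = list(pattern)
            _guard_flanks(seq, start, slen, stype, mirnas[mid], rng)
            taken.append((lo, hi))
            planted.append((mid, uid, start, stype))
        utrs[uid] = "".join(seq)

    truth = SimTruth(planted_sites=planted)
    return mirnas, utrs, truth


def _site_pattern(mirna_seq: str, site_type: str) -> str:
    seed7 = reverse_complement(mirna_seq[1:8])
    seed6 = reverse_complement(mirna_seq[1:7])
    if site_type == "8mer":
        return seed7 + "A"
    if site_type == "7mer-m8":
        return seed7
    if site_type == "7mer-A1":
        return seed6 + "A"
    raise ValueError(f"unknown site type {site_type!r}")


def _guard_flanks(
    seq: np.ndarray,
    start: int,
    slen: int,
    site_type: str,
    mirna_seq: str,
    rng: np.random.Generator,
) -> None:
    """Keep a planted 7mer from reading as an 8mer once flanks are included."""
    m8_comp = reverse_complement(mirna_seq[1:8])[0]
    if site_type == "7mer-m8":
        # a trailing A would make it an 8mer
        end = start + slen
        if end < len(seq) and seq[end] == "A":
            seq[end] = rng.choice([b for b in "CGU"])
    elif site_type == "7mer-A1":
        # a preceding complement of position 8 would make it an 8mer
        if start > 0 and seq[start - 1] == m8_comp:
            seq[start - 1] = rng.choice([b for b in "ACGU" if b != m8_comp])


def simulate_site_features(
    n: int, seed: int = 0, mirna_prefix: str = "mir", utr_prefix: str = "gene"
) -> list[SeedSite]:
    """Random but realistic feature vectors for regression exercises.

    AU content uniform in [0,1], UTR length feature log10 of 100-10000 nt,
    TA feature log10 of 1-1000 matches, SPS uniform in [-14, -6] kcal/mol.
    """
    rng = np.random.default_rng(seed)
    sites = []
    for i in range(n):
        sites.append(
            SeedSite(
                mirna_id=f"{mirna_prefix}-{i + 1:04d}",
                utr_id=f"{utr_prefix}-{i + 1:04d}",
                start=0,
                site_type="7mer-m8",
                au_content=float(rng.uniform(0, 1)),
                utr_len_feature=float(rng.uniform(2, 4)),
                ta_feature=float(np.log10(1 + rng.integers(0, 1000))),
                sps_feature=float(rng.uniform(-14, -6)),
            )
        )
    return sites


def simulate_repression_data(
    sites: Sequence[SeedSite],
    intercept: float,
    coefficients: Sequence[float],
    noise_sd: float,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Site-level repression responses linear in the four context features.

    observed = intercept + coefficients . features + Normal(0, noise_sd)
    """
    coefficients = np.asarray(coefficients, dtype=float)
    if coefficients.shape != (4,):
        raise ValueError("exactly 4 coefficients expected (au, len, ta, sps)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    X = np.vstack([s.feature_vector for s in sites])
    y = intercept + X @ coefficients
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=len(y))
    df = pd.DataFrame(
        {
            "mirna_id": [s.mirna_id for s in sites],
            "utr_id": [s.utr_id for s in sites],
            "au_content": X[:, 0],
            "utr_len_feature": X[:, 1],
            "ta_feature": X[:, 2],
            "sps_feature": X[:, 3],
            "repression": y,
        }
    )
    truth = SimTruth(
        mlr_coefficients=(float(intercept), *(float(c) for c in coefficients))
    )
    return df, truth


def simulate_survival_cohort(
    n: int,
    hazard_ratio: float,
    censor_rate: float = 0.0,
    baseline_hazard: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Exponential survival with two latent groups of different hazard.

    Half the subjects belong to a high-expression group with hazard
    ``baseline_hazard * hazard_ratio``; the other half keep the baseline
    hazard.  Expression is drawn around the latent group (high group shifted
    up) so percentile-based stratification recovers the planted groups.
    Censoring is independent: with probability ``censor_rate`` a subject is
    censored at a uniform fraction of its event time.
    """
    if n < 10:
        raise ValueError("n must be at least 10")
    if hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be positive")
    if not 0.0 <= censor_rate < 1.0:
        raise ValueError("censor_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    group = np.zeros(n, dtype=int)
    group[rng.permutation(n)[: n // 2]] = 1
    hazard = baseline_hazard * hazard_ratio**group
    times = rng.exponential(1.0 / hazard)
    expression = rng.normal(2.0 * group, 0.5)
    event = np.ones(n, dtype=int)
    censored = rng.uniform(size=n) < censor_rate
    event[censored] = 0
    times[censored] *= rng.uniform(size=censored.sum())
    df = pd.DataFrame(
        {
            "subject_id": [f"S{i + 1:04d}" for i in range(n)],
            "time": times,
            "event": event,
            "expression": expression,
        }
    )
    return df, SimTruth(survival_hazard_ratio=float(hazard_ratio))


def simulate_gene_sets(
    genes: Sequence[str],
    n_sets: int = 50,
    set_size_range: tuple[int, int] = (20, 120),
    enriched_in: Optional[Sequence[str]] = None,
    n_enriched_sets: int = 5,
    enrich_frac: float = 0.5,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Random gene-set collection (GMT-style) over a gene universe.

    The first ``n_enriched_sets`` sets draw ``enrich_frac`` of their members
    from ``enriched_in`` (when given), planting true enrichment signal; the
    rest are uniform subsets of the universe.
    """
    rng = np.random.default_rng(seed)
    genes = list(genes)
    enriched_in = list(enriched_in or [])
    sets: dict[str, list[str]] = {}
    for i in range(n_sets):
        size = int(rng.integers(set_size_range[0], min(set_size_range[1], len(genes)) + 1))
        if enriched_in and i < n_enriched_sets:
            k = min(int(round(enrich_frac * size)), len(enriched_in))
            members = set(rng.choice(enriched_in, size=k, replace=False))
            pool = [g for g in genes if g not in members]
            members |= set(rng.choice(pool, size=size - k, replace=False))
        else:
            members = set(rng.choice(genes, size=size, replace=False))
        sets[f"HALLMARK_SYNTH_{i + 1:02d}"] = sorted(members)
    return sets
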