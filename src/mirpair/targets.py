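"""Canonical miRNA seed-site detection and regression-based target scoring.

Site types, with miRNA positions numbered 1..n from the 5' end:

* ``7mer-m8`` — UTR segment equal to the reverse complement of miRNA
  positions 2-8 (7 nt).
* ``7mer-A1`` — reverse complement of positions 2-7 followed by an ``A`` in
  the UTR; the A faces miRNA position 1 regardless of what position 1 is.
* ``8mer``   — reverse complement of positions 2-8 followed by an ``A``.

6mer sites are deliberately not scanned: their repression signal is weak and
they mostly add noise to target prediction.  A locus matching more than one
pattern is reported once with the most specific type (8mer > 7mer-m8 >
7mer-A1).

Each site carries four context features — local AU content of the flanking
region, log10 3'UTR length, log10 target-site abundance across the UTR
universe, and seed-pairing stability from nearest-neighbor thermodynamics —
which a multiple linear regression combines into a repression score; mRNAs
whose summed site score falls below a threshold (default -0.3) are called
putative targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .containers import TargetMap, TargetRelation

__all__ = [
    "SeedSite",
    "MLRModel",
    "scan_seed_sites",
    "compute_site_features",
    "mlr_score",
    "fit_mlr_coefficients",
    "predict_targets",
    "merge_target_maps",
    "reverse_complement",
    "seed_pairing_stability",
    "SITE_LENGTHS",
]

SiteType = Literal["8mer", "7mer-m8", "7mer-A1"]

SITE_LENGTHS: dict[str, int] = {"8mer": 8, "7mer-m8": 7, "7mer-A1": 7}

_COMPLEMENT = str.maketrans("ACGU", "UGCA")

#: RNA nearest-neighbor stacking free energies (Watson-Crick), kcal/mol at
#: 37C, from the standard Turner-group parameter set.  Keys are the top
#: strand dinucleotide read 5'->3'; the bottom strand is its complement.
NN_STACK_DG37: dict[str, float] = {
    "AA": -0.93, "UU": -0.93,
    "AU": -1.10,
    "UA": -1.33,
    "CU": -2.08, "AG": -2.08,
    "CA": -2.11, "UG": -2.11,
    "GU": -2.24, "AC": -2.24,
    "GA": -2.35, "UC": -2.35,
    "CG": -2.36,
    "GG": -3.26, "CC": -3.26,
    "GC": -3.42,
}


def _normalize_rna(seq: str, what: str = "sequence") -> str:
    seq = seq.upper().replace("T", "U")
    bad = set(seq) - set("ACGU")
    if bad:
        raise ValueError(f"{what} contains non-RNA characters: {sorted(bad)}")
    return seq


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SeedSite:
    """A located, typed seed match plus its regression context features.

    ``start`` is the 0-based offset of the site's 5'-most UTR base; the site
    spans ``[start, start + len)`` where len is 8 for 8mer sites and 7
    otherwise.
    """

    mirna_id: str
    utr_id: str
    start: int
    site_type: SiteType
    au_content: Optional[float] = None
    utr_len_feature: Optional[float] = None
    ta_feature: Optional[float] = None
    sps_feature: Optional[float] = None
    mlr_score: Optional[float] = None

    @property
    def end(self) -> int:
        return self.start + SITE_LENGTHS[self.site_type]

    @property
    def feature_vector(self) -> np.ndarray:
        feats = (self.au_content, self.utr_len_feature, self.ta_feature, self.sps_feature)
        if any(f is None for f in feats):
            raise ValueError("site features not populated")
        return np.asarray(feats, dtype=float)


@dataclass
class MLRModel:
    """Linear model over the four site context features.

    score = intercept + b_au*AU + b_len*log10(len) + b_ta*TA + b_sps*SPS

    The default coefficients were fit on this package's own synthetic
    repression generator (the source regression's coefficients are not
    public); signs follow the biology: AU-rich flanks and stabler seed
    pairing (more negative SPS) both push the score down, i.e. toward
    stronger predicted repression.
    """

    intercept: float = 0.0
    coefficients: tuple[float, float, float, float] = (-0.40, 0.05, 0.10, 0.02)
    score_threshold: float = -0.3
    residual_sd: Optional[float] = None

    def __post_init__(self) -> None:
        vals = (self.intercept, *self.coefficients, self.score_threshold)
        if not np.isfinite(vals).all():
            raise ValueError("MLR model parameters must be finite")
        if len(self.coefficients) != 4:
            raise ValueError("exactly 4 coefficients expected (au, len, ta, sps)")


def scan_seed_sites(
    mirna_seq: str,
    utr_seq: str,
    mirna_id: str = "mirna",
    utr_id: str = "utr",
) -> list[SeedSite]:
    """Enumerate all canonical seed sites of one miRNA in one UTR.

    Sites are reported left to right; a locus that satisfies several patterns
    appears once under the most specific type.  A 7mer-m8 immediately
    followed by A is absorbed into the 8mer starting at the same offset, and
    a 7mer-A1 preceded by the complement of miRNA position 8 is absorbed into
    the 8mer starting one base earlier.
    """
    mirna_seq = _normalize_rna(mirna_seq, "miRNA")
    utr_seq = _normalize_rna(utr_seq, "UTR")
    if len(mirna_seq) < 8:
        raise ValueError("miRNA must be at least 8 nt")

    seed7 = reverse_complement(mirna_seq[1:8])  # faces positions 2-8
    seed6 = reverse_complement(mirna_seq[1:7])  # faces positions 2-7
    m8_comp = seed7[0]  # complement of miRNA position 8

    sites: list[SeedSite] = []
    n = len(utr_seq)
    for s in range(n - 6):
        window7 = utr_seq[s : s + 7]
        if window7 == seed7:
            if s + 7 < n and utr_seq[s + 7] == "A":
                sites.append(SeedSite(mirna_id, utr_id, s, "8mer"))
            else:
                sites.append(SeedSite(mirna_id, utr_id, s, "7mer-m8"))
        elif window7 == seed6 + "A":
            # skip if this locus is the tail of an 8mer reported at s-1
            if s > 0 and utr_seq[s - 1] == m8_comp:
                continue
            sites.append(SeedSite(mirna_id, utr_id, s, "7mer-A1"))
    return sites


def seed_pairing_stability(mirna_seq: str) -> float:
    """Stacking free energy (kcal/mol) of the perfect duplex over positions 2-8.

    Sums nearest-neighbor stack terms along the 7-bp seed helix assuming
    perfect Watson-Crick pairing (no G:U); always <= 0, with more negative
    values meaning a stabler seed duplex.
    """
    seed = _normalize_rna(mirna_seq, "miRNA")[1:8]
    if len(seed) != 7:
        raise ValueError("miRNA must be at least 8 nt")
    return float(sum(NN_STACK_DG37[seed[i : i + 2]] for i in range(len(seed) - 1)))


def target_site_abundance(mirna_seq: str, utrome: dict[str, str]) -> int:
    """Total count of the miRNA's 7mer-m8 match over every UTR (overlaps included)."""
    seed7 = reverse_complement(_normalize_rna(mirna_seq, "miRNA")[1:8])
    total = 0
    for seq in utrome.values():
        seq = _normalize_rna(seq, "UTR")
        start = 0
        while True:
            hit = seq.find(seed7, start)
            if hit < 0:
                break
            total += 1
            start = hit + 1
    return total


def compute_site_features(
    site: SeedSite,
    utr_seq: str,
    utrome: dict[str, str],
    mirna_seq: str,
    flank: int = 30,
) -> SeedSite:
    """Populate the four regression features of a located site.

    * AU content: fraction of A/U in the ``flank`` nt on each side of the
      site, truncated at the UTR ends (denominator = bases actually present).
    * UTR length: log10 of the full 3'UTR length.
    * Target-site abundance: log10(1 + count of the miRNA's 7mer-m8 match
      across every UTR in ``utrome``).
    * Seed-pairing stability: nearest-neighbor stacking energy of the seed
      duplex, kcal/mol.
    """
    if flank < 0:
        raise ValueError("flank must be non-negative")
    utr_seq = _normalize_rna(utr_seq, "UTR")
    if site.end > len(utr_seq) or utr_seq[site.start : site.end] == "":
        raise ValueError("site does not lie within the UTR")

    left = utr_seq[max(0, site.start - flank) : site.start]
    right = utr_seq[site.end : site.end + flank]
    flank_seq = left + right
    au = (
        sum(1 for b in flank_seq if b in "AU") / len(flank_seq)
        if flank_seq
        else 0.0
    )
    ta_count = target_site_abundance(mirna_seq, utrome)
    return replace(
        site,
        au_content=au,
        utr_len_feature=float(np.log10(len(utr_seq))),
        ta_feature=float(np.log10(1 + ta_count)),
        sps_feature=seed_pairing_stability(mirna_seq),
    )


def mlr_score(site: SeedSite, model: MLRModel) -> float:
    """Linear score of one site: intercept + coefficients . features."""
    return float(model.intercept + model.coefficients @ site.feature_vector)


def fit_mlr_coefficients(training: pd.DataFrame) -> MLRModel:
    """Ordinary least squares of observed repression on the four site features.

    ``training`` must have columns au_content, utr_len_feature, ta_feature,
    sps_feature and repression, one row per site, at least 20 rows.
    """
    import statsmodels.api as sm

    cols = ["au_content", "utr_len_feature", "ta_feature", "sps_feature"]
    missing = [c for c in cols + ["repression"] if c not in training.columns]
    if missing:
        raise ValueError(f"training table missing columns {missing}")
    if len(training) < 20:
        raise ValueError("at least 20 training rows required")
    X = sm.add_constant(training[cols].to_numpy(dtype=float), has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design: features are collinear or constant")
    fit = sm.OLS(training["repression"].to_numpy(dtype=float), X).fit()
    resid_sd = float(np.sqrt(fit.scale))
    return MLRModel(
        intercept=float(fit.params[0]),
        coefficients=tuple(float(b) for b in fit.params[1:5]),
        residual_sd=resid_sd,
    )


def scan_all_sites(
    mirnas: dict[str, str],
    utrs: dict[str, str],
    model: MLRModel | None = None,
    flank: int = 30,
) -> list[SeedSite]:
    """Scan every (miRNA, UTR) combination, with features and (optional) scores."""
    utrs = {uid: _normalize_rna(seq, "UTR") for uid, seq in utrs.items()}
    sites: list[SeedSite] = []
    for mid, mseq in mirnas.items():
        mseq = _normalize_rna(mseq, "miRNA")
        ta_count = target_site_abundance(mseq, utrs)
        ta_feat = float(np.log10(1 + ta_count))
        sps = seed_pairing_stability(mseq)
        for uid, useq in utrs.items():
            for site in scan_seed_sites(mseq, useq, mid, uid):
                left = useq[max(0, site.start - flank) : site.start]
                right = useq[site.end : site.end + flank]
                flank_seq = left + right
                site.au_content = (
                    sum(1 for b in flank_seq if b in "AU") / len(flank_seq)
                    if flank_seq
                    else 0.0
                )
                site.utr_len_feature = float(np.log10(len(useq)))
                site.ta_feature = ta_feat
                site.sps_feature = sps
                if model is not None:
                    site.mlr_score = mlr_score(site, model)
                sites.append(site)
    return sites


def predict_targets(
    mirnas: dict[str, str],
    utrs: dict[str, str],
    model: MLRModel,
    flank: int = 30,
    aggregate: Literal["sum", "min"] = "sum",
) -> TargetMap:
    """Scan, score, aggregate per (miRNA, UTR) and keep pairs below threshold.

    Aggregation to the mRNA level defaults to the sum of site scores; ``min``
    (the single strongest site) is available as an alternative.
    """
    sites = scan_all_sites(mirnas, utrs, model=model, flank=flank)
    per_pair: dict[tuple[str, str], list[float]] = {}
    for site in sites:
        per_pair.setdefault((site.mirna_id, site.utr_id), []).append(site.mlr_score)
    tm = TargetMap()
    for (mid, uid), scores in per_pair.items():
        total = sum(scores) if aggregate == "sum" else min(scores)
        if total < model.score_threshold:
            tm.add(TargetRelation(mid, uid, "mlr", float(total)))
    return tm


def sites_to_frame(sites: Sequence[SeedSite]) -> pd.DataFrame:
    """BED-like site table: utr_id, start, end, mirna_id:site_type, score, strand."""
    rows = [
        (
            s.utr_id,
            s.start,
            s.end,
            f"{s.mirna_id}:{s.site_type}",
            np.nan if s.mlr_score is None else s.mlr_score,
            "+",
        )
        for s in sites
    ]
    return pd.DataFrame(
        rows, columns=["utr_id", "start", "end", "name", "score", "strand"]
    )


def merge_target_maps(
    validated_lists: Iterable[TargetMap],
    prediction_lists: Iterable[TargetMap],
    targetscan_list: TargetMap | None = None,
    min_support: int = 3,
    ts_threshold: float = 0.2,
    ts_comparison: Literal["gt", "lt"] = "gt",
) -> TargetMap:
    """Compile a target knowledgebase from validated, predicted and scored lists.

    The output is the union of (i) every validated relation, (ii) relations
    predicted by at least ``min_support`` prediction programs, and (iii)
    scored (TargetScan-style) relations whose score passes ``ts_threshold``
    under ``ts_comparison``.  The published merge uses score > 0.2, which is
    sign-inverted relative to the usual context-score convention where more
    negative means stronger; both directions are therefore supported.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    out = TargetMap()
    for vmap in validated_lists:
        for rel in vmap.relations:
            out.add(TargetRelation(rel.mirna_id, rel.gene_id, "validated", rel.score))
    support: dict[tuple[str, str], int] = {}
    for pmap in prediction_lists:
        for key in pmap.keys():  # each program counts once per relation
            support[key] = support.get(key, 0) + 1
    for (mid, gid), n in support.items():
        if n >= min_support:
            out.add(TargetRelation(mid, gid, f"predicted:{n}programs", None))
    if targetscan_list is not None:
        for rel in targetscan_list.relations:
            if rel.score is None:
                continue
            ok = rel.score > ts_threshold if ts_comparison == "gt" else rel.score < ts_threshold
            if ok:
                out.add(TargetRelation(rel.mirna_id, rel.gene_id, "predicted:targetscan", rel.score))
    return out
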