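"""Synthetic adverse-event case reports and masked stratified cohort counts.

Real inputs for this pipeline are a public spontaneous-reporting corpus
(quarterly delimited tables keyed by case ID) and a proprietary
population-level EHR platform; neither ships with the package.  This module
generates stand-ins with known ground truth so every downstream stage can
be tested end to end:

* :func:`generate_case_reports` emits the four FAERS-style tables
  (demographics, drug, indication, reaction) for a corpus in which one
  latent *seed* condition (opioid use disorder) co-occurs with a set of
  planted comorbid diseases at a configurable population lift.  Seed cases
  carry an opioid drug record plus a drug-use-disorder reaction so the
  downstream cohort-flagging heuristic rediscovers exactly the seed set.
* :func:`generate_stratified_cohort` draws per-stratum 2x2 outcome counts
  with a shared (common) odds ratio, optionally masked the way
  population-level platforms suppress small cells.

Generative model for case reports
---------------------------------
Per-case item counts follow zero-truncated Poisson laws whose means are
calibrated so that the *total* expected numbers of diseases, drugs and
reactions per case equal the configured means (defaults 1.37, 2.91 and
3.00).  Background items are drawn without replacement from a Zipf-ranked
marginal.  The seed condition appears with probability ``p_s``; each
planted comorbid has overall marginal ``p_c`` and is included with
conditional probability ``q1 = lift * p_c`` given the seed and
``q0 = p_c (1 - p_s * lift) / (1 - p_s)`` otherwise, which makes the
population lift of every (seed, comorbid) pair exactly ``planted_lift``.
Infeasible targets (``q1 > 1`` or ``q0 < 0``) are rejected, not clipped.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .case_control import StratifiedTable, TwoByTwo, write_stratified_tsv
from .preprocess import CaseReport, CohortLexicon, save_lexicon

__all__ = [
    "ReportGenConfig",
    "PlantedTruth",
    "StratumSpec",
    "CohortGenSpec",
    "generate_case_reports",
    "generate_stratified_cohort",
    "mask_stratified_table",
    "DEFAULT_OPIOIDS",
    "DEFAULT_DISORDER_TERMS",
    "OUD_LABEL",
]

OUD_LABEL = "opioid use disorder"
DEFAULT_OPIOIDS = (
    "buprenorphine",
    "fentanyl",
    "hydrocodone",
    "methadone",
    "morphine",
    "oxycodone",
)
DEFAULT_DISORDER_TERMS = (
    "drug abuse",
    "drug dependence",
    "drug withdrawal syndrome",
    "opioid abuse",
)
_QUARTERS = tuple(f"{y}Q{q}" for y in (2019, 2020) for q in range(1, 5))


@dataclass(frozen=True)
class ReportGenConfig:
    """Study conditions for the synthetic case-report corpus.

    The per-case means default to the calibration anchors of the real
    corpus (2.91 drugs, 1.37 diseases, 3.00 adverse events per report).
    """

    n_cases: int = 100_000
    n_diseases: int = 200
    n_drugs: int = 100
    n_reactions: int = 150
    mean_diseases_per_case: float = 1.37
    mean_drugs_per_case: float = 2.91
    mean_reactions_per_case: float = 3.00
    seed_disease_prevalence: float = 0.05
    n_true_comorbid: int = 10
    planted_lift: float = 4.0
    comorbid_marginal: float = 0.02
    zipf_exponent: float = 1.0
    duplicate_fraction: float = 0.10
    rng_seed: int = 0
    delimiter: str = "$"

    def __post_init__(self):
        if self.n_cases <= 0:
            raise ValueError("n_cases must be positive")
        for name in ("mean_diseases_per_case", "mean_drugs_per_case",
                     "mean_reactions_per_case"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not (0.0 < self.seed_disease_prevalence < 1.0):
            raise ValueError("seed_disease_prevalence must lie in (0, 1)")
        if not (0.0 <= self.duplicate_fraction < 1.0):
            raise ValueError("duplicate_fraction must lie in [0, 1)")
        if self.planted_lift < 1.0:
            raise ValueError("planted_lift must be >= 1")
        if self.n_true_comorbid >= self.n_diseases:
            raise ValueError("n_true_comorbid must be < n_diseases")
        if not (0.0 < self.comorbid_marginal < 1.0):
            raise ValueError("comorbid_marginal must lie in (0, 1)")
        # conditional inclusion probabilities implied by the target lift
        if self.q_given_seed > 1.0:
            raise ValueError(
                "infeasible planted_lift: implied P(comorbid | seed) = "
                f"{self.q_given_seed:.3f} > 1; lower planted_lift or "
                "comorbid_marginal"
            )
        if self.q_given_no_seed < 0.0:
            raise ValueError(
                "infeasible planted_lift: implied P(comorbid | no seed) < 0; "
                "requires planted_lift <= 1 / seed_disease_prevalence = "
                f"{1.0 / self.seed_disease_prevalence:.2f}"
            )
        if self.background_disease_mean <= 1.0:
            raise ValueError(
                "mean_diseases_per_case leaves background mean "
                f"{self.background_disease_mean:.3f} <= 1 after the seed and "
                "planted-comorbid contribution; raise the mean or lower "
                "prevalence/marginals"
            )
        for name, m in (("mean_drugs_per_case", self.background_drug_mean),
                        ("mean_reactions_per_case", self.background_reaction_mean)):
            if m <= 1.0:
                raise ValueError(
                    f"{name} leaves background mean {m:.3f} <= 1 after the "
                    "injected cohort-trigger term"
                )

    # -- analytic calibration ------------------------------------------------
    @property
    def q_given_seed(self) -> float:
        return self.planted_lift * self.comorbid_marginal

    @property
    def q_given_no_seed(self) -> float:
        p_s = self.seed_disease_prevalence
        return self.comorbid_marginal * (1.0 - p_s * self.planted_lift) / (1.0 - p_s)

    @property
    def structural_disease_mean(self) -> float:
        """Expected per-case diseases contributed by seed + planted comorbids."""
        return (self.seed_disease_prevalence
                + self.n_true_comorbid * self.comorbid_marginal)

    @property
    def background_disease_mean(self) -> float:
        return self.mean_diseases_per_case - self.structural_disease_mean

    @property
    def background_drug_mean(self) -> float:
        # seed cases carry exactly one extra (opioid) drug record
        return self.mean_drugs_per_case - self.seed_disease_prevalence

    @property
    def background_reaction_mean(self) -> float:
        return self.mean_reactions_per_case - self.seed_disease_prevalence


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth of a generated corpus, for recovery tests."""

    seed_disease: str
    true_comorbids: frozenset
    planted_lift: float
    marginal_probs: dict

    def __post_init__(self):
        if self.seed_disease in self.true_comorbids:
            raise ValueError("seed disease cannot be its own comorbid")
        for term, p in self.marginal_probs.items():
            if not (0.0 < p < 1.0):
                raise ValueError(f"marginal probability of {term!r} outside (0,1)")


# ---------------------------------------------------------------------------
# samplers

def _ztp_rate(mean: float) -> float:
    """Rate lambda of a zero-truncated Poisson with the given mean (> 1)."""
    if mean <= 1.0:
        raise ValueError("zero-truncated Poisson mean must exceed 1")
    f = lambda lam: lam / (1.0 - math.exp(-lam)) - mean
    return brentq(f, 1e-12, max(10.0 * mean, 10.0))


def _sample_ztp(rng: np.random.Generator, lam: float, n: int) -> np.ndarray:
    x = rng.poisson(lam, n)
    while True:
        zeros = x == 0
        if not zeros.any():
            return x
        x[zeros] = rng.poisson(lam, int(zeros.sum()))


def _zipf_weights(n: int, exponent: float) -> np.ndarray:
    w = np.arange(1, n + 1, dtype=float) ** (-exponent)
    return w / w.sum()


def _weighted_distinct(
    rng: np.random.Generator,
    weights: np.ndarray,
    counts: np.ndarray,
    chunk: int = 20_000,
) -> list[np.ndarray]:
    """Per row i, draw counts[i] distinct indices with Zipf weights.

    Weighted sampling without replacement via the Gumbel-top-k trick,
    vectorized in chunks.
    """
    log_w = np.log(weights)
    vocab = len(weights)
    counts = np.minimum(counts, vocab)
    out: list[np.ndarray] = []
    for start in range(0, len(counts), chunk):
        ks = counts[start:start + chunk]
        g = rng.gumbel(size=(len(ks), vocab))
        order = np.argsort(-(log_w[None, :] + g), axis=1)
        out.extend(order[i, :k] for i, k in enumerate(ks))
    return out


# ---------------------------------------------------------------------------
# case-report generation

def generate_case_reports(
    config: ReportGenConfig,
    out_dir: Optional[Path] = None,
) -> tuple[list[CaseReport], PlantedTruth]:
    """Draw a synthetic case-report corpus; optionally write its file bundle.

    Returns the ground-truth :class:`~comorbnet.preprocess.CaseReport`
    objects (seed cases carry the OUD indication explicitly) plus the
    :class:`PlantedTruth`.  When ``out_dir`` is given, also writes the four
    delimited tables, the raw->canonical vocabulary maps, the cohort
    lexicon, the planted-comorbid gold list and a truth sidecar.  In the
    written indication table the seed condition is latent — seed cases are
    only marked by their opioid-drug and disorder-reaction triggers, which
    the preprocessing heuristic uses to reconstruct the label.
    """
    cfg = config
    rng = np.random.default_rng(cfg.rng_seed)
    n = cfg.n_cases

    comorbids = [f"comorbid_{i:02d}" for i in range(cfg.n_true_comorbid)]
    background_d = [f"disease_{i:03d}" for i in range(cfg.n_diseases - cfg.n_true_comorbid)]
    background_drugs = [f"drug_{i:03d}" for i in range(cfg.n_drugs)]
    background_reacs = [f"reaction_{i:03d}" for i in range(cfg.n_reactions)]

    seed_mask = rng.random(n) < cfg.seed_disease_prevalence
    q = np.where(seed_mask, cfg.q_given_seed, cfg.q_given_no_seed)
    comorbid_mask = rng.random((n, cfg.n_true_comorbid)) < q[:, None]

    k_dis = _sample_ztp(rng, _ztp_rate(cfg.background_disease_mean), n)
    k_drug = _sample_ztp(rng, _ztp_rate(cfg.background_drug_mean), n)
    k_reac = _sample_ztp(rng, _ztp_rate(cfg.background_reaction_mean), n)

    dis_idx = _weighted_distinct(rng, _zipf_weights(len(background_d), cfg.zipf_exponent), k_dis)
    drug_idx = _weighted_distinct(rng, _zipf_weights(len(background_drugs), cfg.zipf_exponent), k_drug)
    reac_idx = _weighted_distinct(rng, _zipf_weights(len(background_reacs), cfg.zipf_exponent), k_reac)

    opioid_pick = rng.integers(0, len(DEFAULT_OPIOIDS), n)
    disorder_pick = rng.integers(0, len(DEFAULT_DISORDER_TERMS), n)
    age_groups = np.asarray(["Junior", "Adult", "Senior"])[
        rng.choice(3, n, p=[0.14, 0.61, 0.25])
    ]
    sexes = np.asarray(["Female", "Male", "Unknown"])[
        rng.choice(3, n, p=[0.54, 0.45, 0.01])
    ]
    quarters = np.asarray(_QUARTERS)[rng.integers(0, len(_QUARTERS), n)]
    dup_mask = rng.random(n) < cfg.duplicate_fraction

    reports: list[CaseReport] = []
    demo_rows, drug_rows, indi_rows, reac_rows = [], [], [], []
    for i in range(n):
        cid = str(10_000_001 + i)
        indications = {background_d[j] for j in dis_idx[i]}
        indications.update(comorbids[j] for j in np.flatnonzero(comorbid_mask[i]))
        drugs = {background_drugs[j] for j in drug_idx[i]}
        reactions = {background_reacs[j] for j in reac_idx[i]}
        if seed_mask[i]:
            drugs.add(DEFAULT_OPIOIDS[opioid_pick[i]])
            reactions.add(DEFAULT_DISORDER_TERMS[disorder_pick[i]])
        written_indications = sorted(indications)  # seed label stays latent
        if seed_mask[i]:
            indications.add(OUD_LABEL)
        reports.append(
            CaseReport(
                case_id=cid,
                drugs=frozenset(drugs),
                indications=frozenset(indications),
                reactions=frozenset(reactions),
                demographics=(age_groups[i], sexes[i]),
            )
        )
        if out_dir is None:
            continue
        quarter = quarters[i]
        drugs_sorted = sorted(drugs)
        reacs_sorted = sorted(reactions)
        if dup_mask[i]:
            # stale earlier version: smaller version key, one reaction missing
            demo_rows.append((cid, 1, quarter, age_groups[i], sexes[i]))
            drug_rows.extend((cid, 1, t.upper()) for t in drugs_sorted)
            indi_rows.extend((cid, 1, t.upper()) for t in written_indications)
            reac_rows.extend((cid, 1, t.upper()) for t in reacs_sorted[:-1])
        version = 2 if dup_mask[i] else 1
        demo_rows.append((cid, version, quarter, age_groups[i], sexes[i]))
        drug_rows.extend((cid, version, t.upper()) for t in drugs_sorted)
        indi_rows.extend((cid, version, t.upper()) for t in written_indications)
        reac_rows.extend((cid, version, t.upper()) for t in reacs_sorted)

    marginals = {OUD_LABEL: cfg.seed_disease_prevalence}
    marginals.update({t: cfg.comorbid_marginal for t in comorbids})
    bg_w = _zipf_weights(len(background_d), cfg.zipf_exponent)
    for term, w in zip(background_d, bg_w):
        # first-order expected occupancy; reporting only
        marginals[term] = min(max(cfg.background_disease_mean * w, 1e-12), 1 - 1e-12)
    truth = PlantedTruth(
        seed_disease=OUD_LABEL,
        true_comorbids=frozenset(comorbids),
        planted_lift=cfg.planted_lift,
        marginal_probs=marginals,
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        sep = cfg.delimiter
        pd.DataFrame(demo_rows, columns=["case_id", "version", "quarter", "age_group", "sex"]
                     ).to_csv(out_dir / "DEMO.txt", sep=sep, index=False)
        pd.DataFrame(drug_rows, columns=["case_id", "version", "drug_raw"]
                     ).to_csv(out_dir / "DRUG.txt", sep=sep, index=False)
        pd.DataFrame(indi_rows, columns=["case_id", "version", "indication_raw"]
                     ).to_csv(out_dir / "INDI.txt", sep=sep, index=False)
        pd.DataFrame(reac_rows, columns=["case_id", "version", "reaction_raw"]
                     ).to_csv(out_dir / "REAC.txt", sep=sep, index=False)
        _write_map(out_dir / "drug_map.tsv",
                   list(background_drugs) + list(DEFAULT_OPIOIDS))
        _write_map(out_dir / "indi_map.tsv",
                   background_d + comorbids + [OUD_LABEL])
        _write_map(out_dir / "reac_map.tsv",
                   background_reacs + list(DEFAULT_DISORDER_TERMS))
        save_lexicon(
            CohortLexicon(frozenset(DEFAULT_OPIOIDS),
                          frozenset(DEFAULT_DISORDER_TERMS), OUD_LABEL),
            out_dir / "lexicon.tsv",
        )
        with open(out_dir / "gold_comorbidities.txt", "w", encoding="utf-8") as fh:
            for term in comorbids:
                fh.write(term + "\n")
        with open(out_dir / "truth.json", "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "seed_disease": truth.seed_disease,
                    "true_comorbids": sorted(truth.true_comorbids),
                    "planted_lift": truth.planted_lift,
                    "marginal_probs": truth.marginal_probs,
                },
                fh,
                indent=1,
                sort_keys=True,
            )

    return reports, truth


def _write_map(path: Path, canonical_terms: Sequence[str]) -> None:
    """Raw->canonical vocabulary map; raw strings are the upper-case forms."""
    with open(path, "w", encoding="utf-8") as fh:
        for term in canonical_terms:
            fh.write(f"{term.upper()}\t{term}\n")


# ---------------------------------------------------------------------------
# stratified cohort generation

@dataclass(frozen=True)
class StratumSpec:
    label: str
    exposed: int
    unexposed: int
    baseline_outcome_odds: float

    def __post_init__(self):
        if self.exposed < 0 or self.unexposed < 0:
            raise ValueError("stratum counts must be non-negative")
        if self.baseline_outcome_odds <= 0:
            raise ValueError("baseline_outcome_odds must be positive")


@dataclass(frozen=True)
class CohortGenSpec:
    """Stratified-cohort generator spec with a shared conditional odds ratio."""

    strata: tuple
    common_or: float = 1.45
    mask_below: int = 10
    round_to: int = 10
    apply_masking: bool = False
    rng_seed: int = 0

    def __post_init__(self):
        if self.common_or <= 0:
            raise ValueError("common_or must be positive")
        if not self.strata:
            raise ValueError("at least one stratum is required")


def generate_stratified_cohort(spec: CohortGenSpec) -> StratifiedTable:
    """Draw outcome counts per stratum at the spec's common odds ratio.

    Within stratum s with baseline outcome odds w, the unexposed outcome
    probability is w/(1+w) and the exposed probability is
    w*OR/(1+w*OR), so the conditional odds ratio is ``common_or`` in every
    stratum.  With ``apply_masking`` the platform-style suppression of
    :func:`mask_stratified_table` is applied.
    """
    rng = np.random.default_rng(spec.rng_seed)
    strata = []
    for st in spec.strata:
        odds0 = st.baseline_outcome_odds
        odds1 = odds0 * spec.common_or
        p0 = odds0 / (1.0 + odds0)
        p1 = odds1 / (1.0 + odds1)
        a = int(rng.binomial(st.exposed, p1))
        c = int(rng.binomial(st.unexposed, p0))
        strata.append(
            (st.label, TwoByTwo(a, st.exposed - a, c, st.unexposed - c))
        )
    table = StratifiedTable(
        strata,
        provenance={"common_or": spec.common_or, "rng_seed": spec.rng_seed},
    )
    if spec.apply_masking:
        table = mask_stratified_table(table, spec.mask_below, spec.round_to)
    return table


def mask_stratified_table(
    s: StratifiedTable, mask_below: int = 10, round_to: int = 10
) -> StratifiedTable:
    """Platform-style de-identification: suppress small cells, round the rest.

    Any cell below ``mask_below`` becomes a suppression marker (``None``);
    remaining cells are rounded half-up to the nearest ``round_to``.
    """
    def cell(v: int):
        if v < mask_below:
            return None
        return ((v + round_to // 2) // round_to) * round_to

    masked = [
        (label, TwoByTwo(cell(t.a), cell(t.b), cell(t.c_), cell(t.d)))
        for label, t in s
    ]
    prov = dict(s.provenance)
    prov.update(mask_below=mask_below, round_to=round_to)
    return StratifiedTable(masked, provenance=prov)


def write_cohort_bundle(spec: CohortGenSpec, table: StratifiedTable, out_dir) -> None:
    """Write the stratified table plus a machine-readable truth sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_stratified_tsv(table, out_dir / "stratified_counts.tsv")
    with open(out_dir / "cohort_truth.json", "w", encoding="utf-8") as fh:
        json.dump(
            {
                "common_or": spec.common_or,
                "mask_below": spec.mask_below,
                "round_to": spec.round_to,
                "apply_masking": spec.apply_masking,
                "rng_seed": spec.rng_seed,
                "strata": [
                    {
                        "label": st.label,
                        "exposed": st.exposed,
                        "unexposed": st.unexposed,
                        "baseline_outcome_odds": st.baseline_outcome_odds,
                    }
                    for st in spec.strata
                ],
            },
            fh,
            indent=1,
            sort_keys=True,
        )
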