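"""Raw adverse-event tables -> de-duplicated, normalized per-case transactions.

Quarterly spontaneous-report tables (demographics, drug, indication,
reaction) are linked by case ID.  A case may be re-submitted in later
quarters; only its latest version is kept.  Raw drug/indication/reaction
strings are mapped to canonical vocabulary terms via user-supplied mapping
tables (the stand-in for an ontology-normalization step), with unmapped
strings dropped and coverage reported.  A heuristic cohort flag injects the
opioid-use-disorder (OUD) label into a case's indications whenever an
opioid drug and a drug-use-disorder term co-occur in that case.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CaseReport",
    "CohortLexicon",
    "TABLE_NAMES",
    "read_faers_tables",
    "deduplicate_cases",
    "load_vocabulary",
    "normalize_terms",
    "assemble_cases",
    "load_lexicon",
    "save_lexicon",
    "flag_oud_cases",
    "build_transactions",
    "write_transactions",
    "read_transactions",
]

TABLE_NAMES = ("demo", "drug", "indi", "reac")
#: raw payload column per table (demo has structured fields instead)
RAW_COLUMNS = {"drug": "drug_raw", "indi": "indication_raw", "reac": "reaction_raw"}


@dataclass(frozen=True)
class CaseReport:
    """One de-duplicated adverse-event case with canonical term sets."""

    case_id: str
    drugs: frozenset
    indications: frozenset
    reactions: frozenset
    demographics: Optional[tuple] = None  # (age_group, sex)


@dataclass(frozen=True)
class CohortLexicon:
    """Terms defining the heuristic OUD cohort.

    A case is flagged when at least one opioid drug name appears among its
    drugs AND at least one drug-use-disorder term appears among its
    indications or reactions; the ``oud_label`` indication is then injected.
    """

    opioid_drugs: frozenset
    disorder_terms: frozenset
    oud_label: str

    def __post_init__(self):
        if not self.opioid_drugs or not self.disorder_terms:
            raise ValueError("lexicon term sets must be non-empty")


def _canon(s: str) -> str:
    return str(s).strip().lower()


def read_faers_tables(
    directory, delimiter: str = "$"
) -> dict[str, pd.DataFrame]:
    """Read the four delimited tables (DEMO/DRUG/INDI/REAC) from a directory."""
    directory = Path(directory)
    tables = {}
    for name in TABLE_NAMES:
        path = directory / f"{name.upper()}.txt"
        if not path.exists():
            raise FileNotFoundError(f"missing table file {path}")
        tables[name] = pd.read_csv(path, sep=delimiter, dtype={"case_id": str})
    return tables


def deduplicate_cases(
    tables: Mapping[str, pd.DataFrame],
) -> tuple[dict[str, pd.DataFrame], dict]:
    """Keep only the latest version of every case.

    "Latest" is the lexicographic maximum of the (quarter, version) key
    taken from the demographics table, quarters being sortable strings like
    ``2020Q3``.  Rows in any table whose version differs from the case's
    maximal version are discarded; row order is otherwise preserved.  Rows
    with a missing version key are dropped with a warning.
    """
    demo = tables["demo"]
    if "version" not in demo.columns or "quarter" not in demo.columns:
        raise ValueError("demographics table must carry version and quarter columns")
    bad = demo["version"].isna() | demo["quarter"].isna()
    if bad.any():
        logger.warning("dropping %d demographics rows with missing version key", bad.sum())
        demo = demo[~bad]

    # maximal (quarter, version) per case
    key = list(zip(demo["quarter"].astype(str), demo["version"].astype(int)))
    keyed = demo.assign(_key=key)
    max_key = keyed.groupby("case_id")["_key"].max()
    max_version = {cid: k[1] for cid, k in max_key.items()}

    out: dict[str, pd.DataFrame] = {}
    report = {"cases": len(max_version)}
    for name, df in tables.items():
        before = len(df)
        if "version" in df.columns:
            missing = df["version"].isna()
            if missing.any():
                logger.warning(
                    "dropping %d %s rows with missing version key", missing.sum(), name
                )
                df = df[~missing]
            keep = [
                int(v) == max_version.get(cid, -1)
                for cid, v in zip(df["case_id"], df["version"].astype(int))
            ]
            df = df[keep]
        out[name] = df.reset_index(drop=True)
        report[f"{name}_rows_in"] = before
        report[f"{name}_rows_out"] = len(out[name])
    return out, report


def load_vocabulary(path) -> dict[str, str]:
    """Load a two-column raw->canonical TSV mapping (keys are case-folded)."""
    mapping: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            raw, canonical = line.split("\t")
            mapping[_canon(raw)] = canonical
    if not mapping:
        raise ValueError(f"empty vocabulary map: {path}")
    return mapping


def normalize_terms(
    tables: Mapping[str, pd.DataFrame],
    maps: Mapping[str, Mapping[str, str]],
) -> tuple[dict[str, pd.DataFrame], dict]:
    """Replace raw strings with canonical terms; drop and count unmapped ones.

    ``maps`` holds one raw->canonical mapping per payload table
    (``drug``/``indi``/``reac``).  Returns normalized tables (payload column
    renamed to ``term``) and a per-table coverage report counting mapped
    vs. total unique raw strings.
    """
    out = {"demo": tables["demo"]}
    coverage: dict[str, dict] = {}
    for name, raw_col in RAW_COLUMNS.items():
        vocab = maps[name]
        if not vocab:
            raise ValueError(f"empty vocabulary map for table {name!r}")
        df = tables[name]
        raws = df[raw_col].astype(str).map(_canon)
        mapped = raws.map(vocab)
        keep = mapped.notna()
        uniq = raws.unique()
        n_mapped_uniq = sum(1 for r in uniq if r in vocab)
        coverage[name] = {
            "unique_raw": len(uniq),
            "unique_mapped": n_mapped_uniq,
            "coverage": n_mapped_uniq / len(uniq) if len(uniq) else 0.0,
            "rows_dropped": int((~keep).sum()),
        }
        kept = df[keep].copy()
        kept["term"] = mapped[keep]
        out[name] = kept.drop(columns=[raw_col]).reset_index(drop=True)
    return out, coverage


def assemble_cases(tables: Mapping[str, pd.DataFrame]) -> list[CaseReport]:
    """Group normalized, de-duplicated tables into one CaseReport per case."""
    demo = tables["demo"]
    per_case: dict[str, dict[str, set]] = {}

    def collect(name: str) -> dict[str, set]:
        df = tables[name]
        groups: dict[str, set] = {}
        for cid, term in zip(df["case_id"], df["term"]):
            groups.setdefault(cid, set()).add(term)
        return groups

    drugs, indis, reacs = collect("drug"), collect("indi"), collect("reac")
    demo_dedup = demo.drop_duplicates(subset="case_id", keep="last")
    reports = []
    for row in demo_dedup.itertuples(index=False):
        cid = row.case_id
        demo_fields = None
        if hasattr(row, "age_group") and hasattr(row, "sex"):
            demo_fields = (row.age_group, row.sex)
        reports.append(
            CaseReport(
                case_id=cid,
                drugs=frozenset(drugs.get(cid, ())),
                indications=frozenset(indis.get(cid, ())),
                reactions=frozenset(reacs.get(cid, ())),
                demographics=demo_fields,
            )
        )
    return reports


def load_lexicon(path) -> CohortLexicon:
    """Read a cohort lexicon TSV with rows ``kind<TAB>term``.

    Kinds: ``opioid_drug``, ``disorder_term``, ``oud_label`` (exactly one).
    """
    opioids, disorders, label = set(), set(), None
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            kind, term = line.split("\t")
            if kind == "opioid_drug":
                opioids.add(term)
            elif kind == "disorder_term":
                disorders.add(term)
            elif kind == "oud_label":
                label = term
            else:
                raise ValueError(f"unknown lexicon row kind {kind!r}")
    if label is None:
        raise ValueError("lexicon is missing an oud_label row")
    return CohortLexicon(frozenset(opioids), frozenset(disorders), label)


def save_lexicon(lexicon: CohortLexicon, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term in sorted(lexicon.opioid_drugs):
            fh.write(f"opioid_drug\t{term}\n")
        for term in sorted(lexicon.disorder_terms):
            fh.write(f"disorder_term\t{term}\n")
        fh.write(f"oud_label\t{lexicon.oud_label}\n")


def flag_oud_cases(
    cases: Iterable[CaseReport], lexicon: CohortLexicon
) -> tuple[list[CaseReport], int]:
    """Inject the OUD label into every case matching the lexicon conjunction.

    Flag iff drugs intersect the opioid list AND (indications union
    reactions) intersect the disorder-term list.  Cases that already carry
    the label keep it (the handful of literal OUD reports are merged with
    the heuristic cohort).  Returns the updated cases and the flagged count.
    """
    out = []
    flagged = 0
    for case in cases:
        hit = bool(case.drugs & lexicon.opioid_drugs) and bool(
            (case.indications | case.reactions) & lexicon.disorder_terms
        )
        if hit:
            flagged += 1
            case = CaseReport(
                case_id=case.case_id,
                drugs=case.drugs,
                indications=case.indications | {lexicon.oud_label},
                reactions=case.reactions,
                demographics=case.demographics,
            )
        out.append(case)
    return out, flagged


def build_transactions(cases: Iterable[CaseReport]) -> list[tuple[str, frozenset]]:
    """One transaction per case = its indication set; empty cases dropped."""
    return [(c.case_id, c.indications) for c in cases if c.indications]


def write_transactions(transactions: Sequence[tuple[str, frozenset]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("case_id\tindications\n")
        for cid, items in transactions:
            fh.write(f"{cid}\t{';'.join(sorted(items))}\n")


def read_transactions(path) -> list[tuple[str, frozenset]]:
    out = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("case_id"):
            raise ValueError(f"unexpected transactions header: {header!r}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            cid, joined = line.split("\t")
            out.append((cid, frozenset(joined.split(";"))))
    return out
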