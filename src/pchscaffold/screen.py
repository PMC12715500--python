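"""Consensus screen for candidate phase-separation scaffold proteins.

Three proteome-wide phase-separation predictors are consumed as score
tables (one of them as a downloaded membership list).  Proteins supported
by at least two predictors form the consensus; merging with published
scaffolds gives the candidate catalog, which is then restricted to
nuclear proteins and classified into subnuclear compartments by keyword
matching.  The final pericentric-heterochromatin candidates are the
triple intersection of (i) predicted PCH scaffolds, (ii) the condensate
pellet proteome (HC_P) and (iii) the PCH proteome.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import TYPE_CHECKING, Iterable, Mapping

import pandas as pd
import yaml

if TYPE_CHECKING:  # pragma: no cover
    from .synthio import AnnotationTable, PredictorScoreSet

#: Predictor short names used in catalog provenance flags.  The two
#: assembly-mode scores of the self/partner predictor count as one tool.
PREDICTOR_NAMES = ("drllps", "psap", "phasepred")

#: Terms whose case-insensitive substring presence in localization or GO
#: text marks a protein as nuclear.  The source annotation states only
#: "annotated subcellular localization", so this vocabulary is a
#: documented, configurable default.
NUCLEAR_VOCAB = ("nucleus", "nuclear", "nucleolus", "chromosome", "chromatin")


def load_keyword_map() -> dict[str, list[str]]:
    """Return the default 15-category compartment keyword map."""
    text = (
        resources.files("pchscaffold")
        .joinpath("data/compartment_keywords.yaml")
        .read_text()
    )
    kw = yaml.safe_load(text)
    return {str(k): [str(t) for t in v] for k, v in kw.items()}


# ---------------------------------------------------------------------------
# domain types


@dataclass
class ScaffoldCatalog:
    """Candidate scaffold catalog: one entry per protein.

    ``entries`` columns: protein_id, predicted_by (semicolon-joined subset
    of :data:`PREDICTOR_NAMES`), support (0-3), published (bool),
    assembly_mode (SaPS/PdPS/none), compartments (semicolon-joined labels).
    """

    entries: pd.DataFrame
    min_support: int = 2

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.entries
        required = {"protein_id", "predicted_by", "support", "published",
                    "assembly_mode", "compartments"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"catalog missing columns: {sorted(missing)}")
        if df["protein_id"].duplicated().any():
            dups = df.loc[df["protein_id"].duplicated(), "protein_id"].tolist()
            raise ValueError(f"duplicate catalog ids: {dups[:5]}")
        for pred_by, support in zip(df["predicted_by"], df["support"]):
            names = [p for p in str(pred_by).split(";") if p]
            if len(names) != int(support):
                raise ValueError("support inconsistent with predicted_by")

    @property
    def ids(self) -> set[str]:
        return set(self.entries["protein_id"])

    def candidates(self) -> set[str]:
        df = self.entries
        keep = (df["support"] >= self.min_support) | df["published"]
        return set(df.loc[keep, "protein_id"])

    def with_compartment(self, label: str) -> set[str]:
        out = set()
        for pid, comp in zip(self.entries["protein_id"],
                             self.entries["compartments"]):
            if label in str(comp).split(";"):
                out.add(pid)
        return out

    def to_tsv(self, path) -> None:
        self.entries.to_csv(path, sep="\t", index=False, na_rep="NA")

    @classmethod
    def from_tsv(cls, path, min_support: int = 2) -> "ScaffoldCatalog":
        df = pd.read_csv(path, sep="\t", comment="#",
                         keep_default_na=False, na_values=[])
        df["support"] = df["support"].astype(int)
        df["published"] = df["published"].map(
            lambda v: str(v).strip().lower() in {"true", "1"})
        return cls(df, min_support=min_support)


@dataclass
class VennCounts:
    """Region counts of a three-set intersection (7 disjoint regions)."""

    only_a: int
    only_b: int
    only_c: int
    ab: int
    ac: int
    bc: int
    abc: int
    n_a: int = 0
    n_b: int = 0
    n_c: int = 0
    labels: tuple[str, str, str] = ("A", "B", "C")

    def __post_init__(self) -> None:
        if self.n_a != self.only_a + self.ab + self.ac + self.abc:
            raise ValueError("set A regions do not sum to |A|")
        if self.n_b != self.only_b + self.ab + self.bc + self.abc:
            raise ValueError("set B regions do not sum to |B|")
        if self.n_c != self.only_c + self.ac + self.bc + self.abc:
            raise ValueError("set C regions do not sum to |C|")

    @property
    def union_size(self) -> int:
        return (self.only_a + self.only_b + self.only_c
                + self.ab + self.ac + self.bc + self.abc)

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "only_a": self.only_a, "only_b": self.only_b,
            "only_c": self.only_c, "ab": self.ab, "ac": self.ac,
            "bc": self.bc, "abc": self.abc,
            "n_a": self.n_a, "n_b": self.n_b, "n_c": self.n_c,
            "union": self.union_size,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# operations


def top_n_candidates(scores: "PredictorScoreSet | Mapping[str, float]",
                     n: int) -> set[str]:
    """Top-``n`` protein ids by score.

    Ties are broken by (score descending, protein_id ascending) and cut at
    the boundary so the result has exactly ``min(n, table size)`` members.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    entries = getattr(scores, "entries", scores)
    if not isinstance(entries, Mapping):
        raise TypeError("scores must provide a protein_id -> score mapping")
    items = []
    for pid, s in entries.items():
        s = float(s)
        if not pd.notna(s):
            raise ValueError(f"non-numeric score for {pid!r}")
        items.append((pid, s))
    items.sort(key=lambda kv: (-kv[1], kv[0]))
    return {pid for pid, _ in items[:n]}


def consensus_vote(candidate_sets: Iterable[set[str]],
                   min_support: int = 2) -> set[str]:
    """Ids appearing in at least ``min_support`` of the candidate sets."""
    sets = [set(s) for s in candidate_sets]
    if not sets:
        raise ValueError("need at least one candidate set")
    if not 1 <= min_support <= len(sets):
        raise ValueError(
            f"min_support must be in [1, {len(sets)}], got {min_support}")
    counts: dict[str, int] = {}
    for s in sets:
        for pid in s:
            counts[pid] = counts.get(pid, 0) + 1
    return {pid for pid, c in counts.items() if c >= min_support}


def build_catalog(consensus: set[str],
                  per_predictor: Mapping[str, set[str]],
                  published: set[str],
                  min_support: int = 2) -> ScaffoldCatalog:
    """Merge the predictor consensus with published scaffolds.

    The catalog holds one entry per protein in ``consensus | published``
    with provenance flags: which predictors supported it and whether it is
    a published scaffold.
    """
    unknown = set(per_predictor) - set(PREDICTOR_NAMES)
    if unknown:
        raise ValueError(f"unknown predictor names: {sorted(unknown)}")
    union_pred: set[str] = set().union(*per_predictor.values()) \
        if per_predictor else set()
    if not set(consensus) <= union_pred:
        raise ValueError("consensus ids must come from the predictor sets")
    rows = []
    for pid in sorted(set(consensus) | set(published)):
        pred_by = sorted(name for name in PREDICTOR_NAMES
                         if pid in per_predictor.get(name, ()))
        rows.append({
            "protein_id": pid,
            "predicted_by": ";".join(pred_by),
            "support": len(pred_by),
            "published": pid in published,
            "assembly_mode": "none",
            "compartments": "",
        })
    df = pd.DataFrame(rows, columns=["protein_id", "predicted_by", "support",
                                     "published", "assembly_mode",
                                     "compartments"])
    return ScaffoldCatalog(df, min_support=min_support)


def _protein_text(annotations: "AnnotationTable") -> dict[str, str]:
    df = annotations.df
    return {
        pid: f"{loc} {go}"
        for pid, loc, go in zip(df["protein_id"], df["localization_text"],
                                df["go_text"])
    }


def filter_nuclear(catalog: ScaffoldCatalog,
                   annotations: "AnnotationTable",
                   vocabulary: Iterable[str] = NUCLEAR_VOCAB
                   ) -> ScaffoldCatalog:
    """Keep catalog entries annotated as nuclear.

    A protein is nuclear when its localization or GO text contains any
    vocabulary term (case-insensitive substring).
    """
    text = _protein_text(annotations)
    missing = [pid for pid in catalog.entries["protein_id"]
               if pid not in text]
    if missing:
        raise KeyError(f"unannotated catalog ids: {sorted(missing)[:10]}")
    vocab = [v.lower() for v in vocabulary]
    keep = [
        any(v in text[pid].lower() for v in vocab)
        for pid in catalog.entries["protein_id"]
    ]
    kept = catalog.entries.loc[keep].reset_index(drop=True)
    return ScaffoldCatalog(kept, min_support=catalog.min_support)


def classify_compartments(catalog: ScaffoldCatalog,
                          annotations: "AnnotationTable",
                          keyword_map: Mapping[str, list[str]] | None = None
                          ) -> ScaffoldCatalog:
    """Fill the catalog's compartment labels by keyword matching.

    Matching is case-insensitive plain substring over the protein's
    localization and GO text; a protein may carry several labels and
    proteins with no hit carry the empty set.  Idempotent and independent
    of row order.
    """
    if keyword_map is None:
        keyword_map = load_keyword_map()
    if not keyword_map:
        raise ValueError("keyword_map is empty")
    text = _protein_text(annotations)
    lowered = {label: [t.lower() for t in terms]
               for label, terms in keyword_map.items()}
    labels = []
    for pid in catalog.entries["protein_id"]:
        blob = text.get(pid, "").lower()
        hits = sorted(label for label, terms in lowered.items()
                      if any(t in blob for t in terms))
        labels.append(";".join(hits))
    df = catalog.entries.copy()
    df["compartments"] = labels
    return ScaffoldCatalog(df, min_support=catalog.min_support)


def keyword_classes(annotations: "AnnotationTable",
                    keyword_map: Mapping[str, list[str]] | None = None
                    ) -> dict[str, set[str]]:
    """Map each compartment label to the annotated ids matching it.

    Same case-insensitive substring rule as :func:`classify_compartments`,
    applied to the whole annotation table rather than a catalog.
    """
    if keyword_map is None:
        keyword_map = load_keyword_map()
    if not keyword_map:
        raise ValueError("keyword_map is empty")
    text = _protein_text(annotations)
    out: dict[str, set[str]] = {label: set() for label in keyword_map}
    for pid, blob in text.items():
        blob = blob.lower()
        for label, terms in keyword_map.items():
            if any(t.lower() in blob for t in terms):
                out[label].add(pid)
    return out


def classify_assembly(self_scores: Mapping[str, float],
                      partner_scores: Mapping[str, float],
                      self_cut: int = 1000,
                      partner_cut: int = 1000) -> dict[str, str]:
    """Label proteins SaPS / PdPS / none from the two assembly scores.

    "High" means membership in the top-``cut`` rank list of a score.
    High in both, or high in self only, maps to self-assembling phase
    separation (SaPS); high in partner only maps to partner-dependent
    phase separation (PdPS); neither maps to "none".
    """
    if set(self_scores) != set(partner_scores):
        raise ValueError("self and partner scores cover different proteins")
    high_self = top_n_candidates(dict(self_scores), self_cut)
    high_partner = top_n_candidates(dict(partner_scores), partner_cut)
    out = {}
    for pid in self_scores:
        if pid in high_self:
            out[pid] = "SaPS"
        elif pid in high_partner:
            out[pid] = "PdPS"
        else:
            out[pid] = "none"
    return out


def apply_assembly_modes(catalog: ScaffoldCatalog,
                         modes: Mapping[str, str]) -> ScaffoldCatalog:
    """Return a catalog with assembly_mode filled from ``modes``."""
    df = catalog.entries.copy()
    df["assembly_mode"] = [modes.get(pid, "none")
                           for pid in df["protein_id"]]
    return ScaffoldCatalog(df, min_support=catalog.min_support)


def triple_intersect(pch_pred: set[str], hc_p: set[str],
                     pch_proteome: set[str]
                     ) -> tuple[set[str], VennCounts]:
    """Three-way intersection yielding the final PCH scaffold candidates.

    Returns the candidate set (proteins in all three inputs) and the full
    seven-region Venn tabulation.
    """
    a, b, c = set(pch_pred), set(hc_p), set(pch_proteome)
    abc = a & b & c
    counts = VennCounts(
        only_a=len(a - b - c), only_b=len(b - a - c), only_c=len(c - a - b),
        ab=len((a & b) - c), ac=len((a & c) - b), bc=len((b & c) - a),
        abc=len(abc), n_a=len(a), n_b=len(b), n_c=len(c),
        labels=("PCH_prediction", "HC_P", "PCH_proteome"),
    )
    return abc, counts
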