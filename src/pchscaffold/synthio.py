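"""Synthetic inputs with planted ground truth for the whole pipeline.

Every generator here emulates one class of raw input the screen consumes:

* protein annotation tables whose localization/GO text embeds compartment
  keywords inside longer sentences,
* proteome-wide predictor score tables with a planted scaffold signal,
* DIA-style protein-intensity matrices (log-normal intensities,
  fraction-specific enrichment effects, abundance-dependent missingness),
* two-compartment half-bleach exchange traces with a tunable boundary,
* nucleus images with bright chromocenter foci, and
* linear standard-curve measurements.

Generators are bit-reproducible given ``(params, seed)``; each draws from
its own named random stream so adding a generator never shifts another's
output, and each output records ``(params, seed)`` in a provenance block.
Missing values are explicit (NaN in memory, ``NA`` on disk); a zero raw
intensity is invalid.
"""
from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy.integrate import solve_ivp
from scipy.special import expit

from .screen import load_keyword_map

MISSING = "NA"

#: Labels accepted in ``compartment_mix`` that abbreviate keyword-map keys.
COMPARTMENT_ALIASES = {
    "pericentric": "pericentric_heterochromatin",
    "speckle": "nucleus_speckle",
    "inactive_x": "inactive_x_chromosome",
}

_DISTRACTOR_SENTENCES = [
    "Detected in the cytoplasm near the plasma membrane.",
    "Associated with the Golgi apparatus and secretory vesicles.",
    "Mitochondrion matrix enzyme of the citrate cycle.",
    "Extracellular matrix glycoprotein secreted upon stimulation.",
    "Endoplasmic reticulum lumen chaperone activity.",
    "Peroxisome membrane anchored transporter.",
    "Cytoskeleton binding protein of the cell cortex.",
]

_NUCLEAR_SENTENCES = [
    "Nucleus.",
    "Localizes to the cell nucleus in interphase.",
    "Chromosome-associated factor enriched on mitotic chromatin.",
]

_DEFAULT_TISSUES = ("brain", "muscle", "liver", "kidney", "spleen",
                    "lung", "heart", "ileum")


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Independent, named random stream derived from the run seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF,
                                zlib.crc32(stream.encode())]))


def _provenance(generator: str, params: Mapping, seed: int) -> dict:
    clean = {}
    for k, v in params.items():
        if isinstance(v, Mapping):
            clean[k] = {str(kk): vv for kk, vv in v.items()}
        elif isinstance(v, (set, frozenset)):
            clean[k] = sorted(v)
        elif isinstance(v, np.ndarray):
            clean[k] = v.tolist()
        else:
            clean[k] = v
    return {"generator": generator, "seed": int(seed), "params": clean}


# ---------------------------------------------------------------------------
# domain types


@dataclass
class AnnotationTable:
    """Per-protein identifiers, free-text annotation and numeric features.

    ``df`` columns: protein_id, gene_symbol, localization_text, go_text
    (semicolon-joined free-text terms), has_cc, has_znf, disorder_fraction,
    true_compartment (generator ground truth, empty for real data) and one
    ``ppm_<tissue>`` column per tissue when abundances are present.
    """

    df: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.df
        if df["protein_id"].duplicated().any():
            raise ValueError("protein_id values must be unique")
        frac = df["disorder_fraction"].astype(float)
        if ((frac < 0) | (frac > 1)).any():
            raise ValueError("disorder_fraction must lie in [0, 1]")
        for col in self.ppm_columns:
            vals = df[col].astype(float)
            if (vals.dropna() < 0).any():
                raise ValueError(f"negative ppm values in {col}")

    @property
    def ids(self) -> list[str]:
        return list(self.df["protein_id"])

    @property
    def ppm_columns(self) -> list[str]:
        return [c for c in self.df.columns if c.startswith("ppm_")]

    def tissue_ppm(self, protein_id: str) -> dict[str, float]:
        row = self.df.set_index("protein_id").loc[protein_id]
        return {c[len("ppm_"):]: float(row[c]) for c in self.ppm_columns}

    def ids_with_compartment(self, label: str) -> set[str]:
        """Ground-truth ids the generator assigned to ``label``."""
        df = self.df
        return set(df.loc[df["true_compartment"] == label, "protein_id"])

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False, na_rep=MISSING)

    @classmethod
    def from_tsv(cls, path) -> "AnnotationTable":
        df = pd.read_csv(path, sep="\t", comment="#",
                         keep_default_na=False,
                         na_values=[MISSING])
        for col in ("has_cc", "has_znf"):
            df[col] = df[col].map(
                lambda v: str(v).strip().lower() in {"true", "1"})
        if "true_compartment" not in df.columns:
            df["true_compartment"] = ""
        return cls(df)


@dataclass
class PredictorScoreSet:
    """One predictor's output: either numeric scores or a membership list."""

    predictor_name: str
    entries: dict[str, float] | None = None
    members: set[str] | None = None

    _VALID = ("drllps_list", "psap", "phasepred_self", "phasepred_partner")

    def __post_init__(self) -> None:
        if self.predictor_name not in self._VALID:
            raise ValueError(f"unknown predictor {self.predictor_name!r}")
        if (self.entries is None) == (self.members is None):
            raise ValueError("provide exactly one of entries or members")
        if self.entries is not None:
            bad = [pid for pid, s in self.entries.items()
                   if not np.isfinite(float(s))]
            if bad:
                raise ValueError(f"non-finite scores for {bad[:5]}")

    def to_tsv(self, path) -> None:
        if self.entries is not None:
            df = pd.DataFrame({"protein_id": list(self.entries),
                               "score": list(self.entries.values())})
        else:
            df = pd.DataFrame({"protein_id": sorted(self.members)})
        df.to_csv(path, sep="\t", index=False, na_rep=MISSING)

    @classmethod
    def from_tsv(cls, path, predictor_name: str) -> "PredictorScoreSet":
        df = pd.read_csv(path, sep="\t", comment="#")
        if "score" in df.columns:
            return cls(predictor_name,
                       entries=dict(zip(df["protein_id"], df["score"])))
        return cls(predictor_name, members=set(df["protein_id"]))


@dataclass
class IntensityMatrix:
    """Proteins x samples intensity matrix with sample metadata.

    ``values`` is indexed by protein id; columns are sample ids of the form
    ``<fraction>.r<replicate>``.  ``samples`` carries the parsed metadata.
    Missing measurements are NaN; raw-scale values must be positive.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    scale: str = "raw"
    truth: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.scale not in ("raw", "log2"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if list(self.values.columns) != list(self.samples["sample_id"]):
            raise ValueError("values columns and sample metadata disagree")
        if (self.samples["replicate"].astype(int) < 1).any():
            raise ValueError("replicate indices must be positive")
        if self.scale == "raw":
            vals = self.values.to_numpy(dtype=float)
            if np.nanmin(vals, initial=np.inf) <= 0:
                raise ValueError("raw intensities must be > 0 where present")

    @property
    def proteins(self) -> list[str]:
        return list(self.values.index)

    def sample_ids(self, fraction: str) -> list[str]:
        df = self.samples
        out = list(df.loc[df["fraction"] == fraction, "sample_id"])
        if not out:
            raise KeyError(f"unknown fraction {fraction!r}")
        return out

    @property
    def fractions(self) -> list[str]:
        return list(dict.fromkeys(self.samples["fraction"]))

    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(self.values.copy(), self.samples.copy(),
                               self.scale, dict(self.truth),
                               dict(self.provenance))

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.insert(0, "protein_id", out.index)
        out.to_csv(path, sep="\t", index=False, na_rep=MISSING)

    @classmethod
    def from_tsv(cls, path, scale: str = "raw") -> "IntensityMatrix":
        df = pd.read_csv(path, sep="\t", comment="#",
                         keep_default_na=False, na_values=[MISSING])
        df = df.set_index("protein_id")
        samples = _parse_sample_ids(df.columns)
        return cls(df.astype(float), samples, scale=scale)


def _parse_sample_ids(sample_ids: Iterable[str]) -> pd.DataFrame:
    rows = []
    for sid in sample_ids:
        if ".r" not in sid:
            raise ValueError(f"sample id {sid!r} not <fraction>.r<replicate>")
        fraction, rep = sid.rsplit(".r", 1)
        rows.append({"sample_id": sid, "fraction": fraction,
                     "replicate": int(rep)})
    return pd.DataFrame(rows, columns=["sample_id", "fraction", "replicate"])


@dataclass
class FrapTrace:
    """One half-bleach time course (both compartment halves)."""

    time: np.ndarray
    bleached: np.ndarray
    nonbleached: np.ndarray
    n_pre: int

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.bleached = np.asarray(self.bleached, dtype=float)
        self.nonbleached = np.asarray(self.nonbleached, dtype=float)
        n = len(self.time)
        if len(self.bleached) != n or len(self.nonbleached) != n:
            raise ValueError("trace arrays must share one length")
        if not 1 <= self.n_pre < n:
            raise ValueError("need 1 <= n_pre < trace length")
        if (self.bleached < 0).any() or (self.nonbleached < 0).any():
            raise ValueError("intensities must be non-negative")


@dataclass
class FrapTraceSet:
    """A condition's half-bleach traces plus (synthetic) truth parameters."""

    traces: list[FrapTrace]
    condition: str = ""
    truth: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        rows = []
        for i, tr in enumerate(self.traces):
            for half, series in (("bleached", tr.bleached),
                                 ("nonbleached", tr.nonbleached)):
                for t, v in zip(tr.time, series):
                    rows.append((i, t, half, v, tr.n_pre))
        pd.DataFrame(rows, columns=["trace_id", "t", "half", "intensity",
                                    "n_pre"]).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, condition: str = "") -> "FrapTraceSet":
        df = pd.read_csv(path, comment="#")
        traces = []
        for tid, grp in df.groupby("trace_id", sort=True):
            b = grp[grp["half"] == "bleached"].sort_values("t")
            n = grp[grp["half"] == "nonbleached"].sort_values("t")
            traces.append(FrapTrace(b["t"].to_numpy(),
                                    b["intensity"].to_numpy(),
                                    n["intensity"].to_numpy(),
                                    int(grp["n_pre"].iloc[0])))
        return cls(traces, condition=condition)


@dataclass
class NucleusImage:
    """Multi-channel nucleus image with optional planted truth masks."""

    channels: dict[str, np.ndarray]
    pixel_size: tuple[float, ...]
    truth: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "dapi" not in self.channels:
            raise ValueError("a 'dapi' channel is required")
        shapes = {c.shape for c in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError("channels must share one shape")
        if any(p <= 0 for p in self.pixel_size):
            raise ValueError("pixel sizes must be positive")

    @property
    def shape(self) -> tuple[int, ...]:
        return next(iter(self.channels.values())).shape

    def to_tiff(self, path) -> None:
        """Multi-page TIFF (channels stacked) + JSON sidecar."""
        path = str(path)
        names = sorted(self.channels)
        stack = np.stack([self.channels[n].astype(np.float32)
                          for n in names])
        tifffile.imwrite(path, stack)
        meta = {"channel_names": names,
                "pixel_size": list(self.pixel_size),
                "shape": list(self.shape)}
        with open(path + ".json", "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)

    @classmethod
    def from_tiff(cls, path) -> "NucleusImage":
        path = str(path)
        stack = tifffile.imread(path)
        with open(path + ".json") as fh:
            meta = json.load(fh)
        channels = {name: np.asarray(stack[i], dtype=float)
                    for i, name in enumerate(meta["channel_names"])}
        return cls(channels, tuple(meta["pixel_size"]))


@dataclass
class StandardCurve:
    """Known quantities vs measured intensities with an optional OLS fit."""

    levels: np.ndarray
    readings: np.ndarray
    slope: float | None = None
    intercept: float | None = None
    r2: float | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=float)
        self.readings = np.asarray(self.readings, dtype=float)
        if len(np.unique(self.levels)) < 2:
            raise ValueError("need >= 2 distinct levels")
        if not np.isfinite(self.readings).all():
            raise ValueError("readings must be finite")

    def to_csv(self, path) -> None:
        pd.DataFrame({"level": self.levels,
                      "reading": self.readings}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "StandardCurve":
        df = pd.read_csv(path, comment="#")
        return cls(df["level"].to_numpy(), df["reading"].to_numpy())


# ---------------------------------------------------------------------------
# generators


def gen_annotations(n_proteins: int,
                    compartment_mix: Mapping[str, float],
                    seed: int,
                    p_cc: float = 0.25,
                    p_znf: float = 0.2,
                    disorder_beta: tuple[float, float] = (2.0, 3.0),
                    with_tissue_ppm: bool = True,
                    tissues: Sequence[str] = _DEFAULT_TISSUES
                    ) -> AnnotationTable:
    """Annotation table with compartment keywords planted per the mix.

    Each protein is assigned at most one ground-truth compartment with the
    given proportions (remaining mass means "no compartment").  Its text
    embeds one keyword of that compartment, verbatim and case preserved,
    inside a longer sentence, alongside distractor sentences, so that
    substring matching is genuinely exercised.  Coiled-coil / zinc-finger
    flags are Bernoulli(p_cc/p_znf); disorder fractions are
    Beta(*disorder_beta*); tissue abundances are log-normal ppm.
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    keyword_map = load_keyword_map()
    mix: dict[str, float] = {}
    for label, p in compartment_mix.items():
        label = COMPARTMENT_ALIASES.get(label, label)
        if label not in keyword_map:
            raise ValueError(f"unknown compartment label {label!r}")
        if not 0.0 <= p <= 1.0:
            raise ValueError("proportions must lie in [0, 1]")
        mix[label] = float(p)
    total = sum(mix.values())
    if total > 1.0 + 1e-12:
        raise ValueError("compartment proportions sum to more than 1")

    rng = _rng(seed, "gen_annotations")
    labels = list(mix) + [""]
    probs = list(mix.values()) + [max(0.0, 1.0 - total)]
    probs = np.asarray(probs) / np.sum(probs)
    assigned = rng.choice(len(labels), size=n_proteins, p=probs)

    rows = []
    for i in range(n_proteins):
        pid = f"P{i:05d}"
        label = labels[assigned[i]]
        loc_parts = []
        go_terms = []
        if label:
            kw = keyword_map[label][rng.integers(len(keyword_map[label]))]
            go_terms.append(f"component of the {kw} region")
            loc_parts.append(str(rng.choice(_NUCLEAR_SENTENCES)))
        else:
            # background proteins: nuclear or not, no compartment keyword
            if rng.random() < 0.4:
                loc_parts.append(str(rng.choice(_NUCLEAR_SENTENCES)))
            else:
                loc_parts.append(str(rng.choice(_DISTRACTOR_SENTENCES)))
        loc_parts.append(str(rng.choice(_DISTRACTOR_SENTENCES)))
        go_terms.append("protein binding")
        row = {
            "protein_id": pid,
            "gene_symbol": f"Gene{i}",
            "localization_text": " ".join(loc_parts),
            "go_text": ";".join(go_terms),
            "has_cc": bool(rng.random() < p_cc),
            "has_znf": bool(rng.random() < p_znf),
            "disorder_fraction": float(rng.beta(*disorder_beta)),
            "true_compartment": label,
        }
        if with_tissue_ppm:
            for t in tissues:
                row[f"ppm_{t}"] = float(np.exp(rng.normal(2.0, 1.0)))
        rows.append(row)
    df = pd.DataFrame(rows)
    prov = _provenance("gen_annotations",
                       {"n_proteins": n_proteins, "compartment_mix": mix,
                        "p_cc": p_cc, "p_znf": p_znf,
                        "disorder_beta": list(disorder_beta),
                        "tissues": list(tissues)}, seed)
    return AnnotationTable(df, provenance=prov)


def gen_predictor_scores(annotations: AnnotationTable,
                         planted_scaffolds: set[str],
                         effect: float,
                         seed: int) -> list[PredictorScoreSet]:
    """Predictor score tables with the planted scaffolds shifted upward.

    Background scores are standard normal in every predictor; planted ids
    are shifted by ``+effect``.  Four score sets are emitted: the
    membership-list predictor (scored here, consumed as its top ranks),
    the single-score predictor, and the self/partner pair of the two-score
    predictor.
    """
    ids = annotations.ids
    unknown = set(planted_scaffolds) - set(ids)
    if unknown:
        raise KeyError(f"planted ids not annotated: {sorted(unknown)[:10]}")
    if effect < 0:
        raise ValueError("effect must be >= 0")
    out = []
    for name in ("drllps_list", "psap", "phasepred_self",
                 "phasepred_partner"):
        rng = _rng(seed, f"gen_predictor_scores/{name}")
        scores = rng.standard_normal(len(ids))
        entries = {}
        for pid, s in zip(ids, scores):
            entries[pid] = float(s + (effect if pid in planted_scaffolds
                                      else 0.0))
        out.append(PredictorScoreSet(name, entries=entries))
    return out


def gen_dia_experiment(annotations: AnnotationTable,
                       design: Sequence[tuple[str, int]],
                       params: Mapping | None = None,
                       seed: int = 0) -> IntensityMatrix:
    """DIA-style raw intensity matrix with planted enrichment and dropout.

    Per-protein baseline log2 intensities are normal
    (``baseline_mean`` +/- ``baseline_sd``); replicate measurements add
    ``base_sd`` noise; ``enrichment_effects`` maps
    ``(protein_class, fraction) -> log2 shift`` where a protein class is a
    ground-truth compartment label, a single protein id or ``"all"``.
    The probability that a measurement is missing is a decreasing logistic
    function of its log2 intensity with the stated midpoint and slope
    (slope 0 gives probability 1/2 everywhere).  Truth shifts are stored
    in ``.truth["shifts"]`` for recovery tests.
    """
    p = {"base_sd": 0.5, "baseline_mean": 20.0, "baseline_sd": 2.0,
         "enrichment_effects": {}, "dropout_midpoint": 16.0,
         "dropout_slope": 1.0}
    p.update(params or {})
    if p["base_sd"] < 0 or p["baseline_sd"] < 0:
        raise ValueError("standard deviations must be >= 0")
    if any(n < 1 for _, n in design):
        raise ValueError("replicate counts must be >= 1")

    ids = annotations.ids
    id_set = set(ids)
    comp_labels = set(annotations.df["true_compartment"]) - {""}

    known_labels = comp_labels | set(load_keyword_map())

    def resolve_class(cls_label: str) -> set[str]:
        if cls_label == "all":
            return id_set
        if cls_label in known_labels:  # may legitimately be empty
            return annotations.ids_with_compartment(cls_label)
        if cls_label in id_set:
            return {cls_label}
        raise KeyError(f"unknown protein class {cls_label!r}")

    # (fraction -> per-protein shift vector)
    shift = {fr: np.zeros(len(ids)) for fr, _ in design}
    index = {pid: i for i, pid in enumerate(ids)}
    for (cls_label, fraction), delta in dict(
            p["enrichment_effects"]).items():
        if fraction not in shift:
            raise KeyError(f"fraction {fraction!r} not in the design")
        for pid in resolve_class(cls_label):
            shift[fraction][index[pid]] += float(delta)

    rng = _rng(seed, "gen_dia_experiment")
    baseline = rng.normal(p["baseline_mean"], p["baseline_sd"], len(ids))
    cols, meta = [], []
    data = {}
    for fraction, n_rep in design:
        for rep in range(1, n_rep + 1):
            sid = f"{fraction}.r{rep}"
            x = baseline + shift[fraction] + rng.normal(
                0.0, p["base_sd"], len(ids))
            p_miss = expit(-p["dropout_slope"] * (x - p["dropout_midpoint"]))
            missing = rng.random(len(ids)) < p_miss
            raw = np.exp2(x)
            raw[missing] = np.nan
            data[sid] = raw
            cols.append(sid)
            meta.append({"sample_id": sid, "fraction": fraction,
                         "replicate": rep})
    values = pd.DataFrame(data, index=ids)[cols]
    samples = pd.DataFrame(meta)
    truth = {"shifts": {fr: dict(zip(ids, shift[fr])) for fr in shift},
             "baseline_log2": dict(zip(ids, baseline))}
    prov = _provenance("gen_dia_experiment",
                       {"design": [list(d) for d in design],
                        **{k: v for k, v in p.items()
                           if k != "enrichment_effects"},
                        "enrichment_effects": {
                            f"{c}|{f}": d for (c, f), d in
                            dict(p["enrichment_effects"]).items()}},
                       seed)
    return IntensityMatrix(values, samples, scale="raw", truth=truth,
                           provenance=prov)


def exchange_matrix(k_intra: float, k_boundary: float,
                    v_surround: float = 20.0) -> np.ndarray:
    """Rate matrix of the three-pool exchange system.

    State = concentrations (bleached half, nonbleached half, surroundings).
    The two halves exchange at ``k_intra``; each half exchanges with the
    surrounding pool at ``k_boundary``.  The surroundings have relative
    volume ``v_surround`` so total fluorescence
    ``c_b + c_n + v_surround * c_s`` is conserved.
    """
    if k_intra < 0 or k_boundary < 0:
        raise ValueError("rates must be >= 0")
    if v_surround <= 0:
        raise ValueError("v_surround must be > 0")
    ki, kb, v = float(k_intra), float(k_boundary), float(v_surround)
    return np.array([
        [-(ki + kb), ki, kb],
        [ki, -(ki + kb), kb],
        [kb / v, kb / v, -2.0 * kb / v],
    ])


def gen_frap_traces(params: Mapping | None = None,
                    seed: int = 0) -> FrapTraceSet:
    """Half-bleach traces from the three-pool exchange model plus noise.

    The bleached half is instantaneously depleted by ``bleach_depth`` at
    frame ``n_pre``; both halves then relax by numerically integrating the
    linear exchange system (tight-tolerance Runge-Kutta).  Gaussian read
    noise is added last, after scaling to a per-trace raw intensity.
    With ``bleach_depth = 0`` and ``noise_sd = 0`` total fluorescence is
    conserved and both halves stay constant.
    """
    p = {"k_intra": 0.5, "k_boundary": 0.05, "bleach_depth": 0.8,
         "noise_sd": 0.02, "n_pre": 9, "n_post": 130, "dt": 1.3,
         "v_surround": 20.0, "n_traces": 1, "base_intensity": 1000.0,
         "condition": "synthetic"}
    p.update(params or {})
    if p["dt"] <= 0:
        raise ValueError("dt must be > 0")
    if not 0.0 <= p["bleach_depth"] <= 1.0:
        raise ValueError("bleach_depth must lie in [0, 1]")
    if p["noise_sd"] < 0:
        raise ValueError("noise_sd must be >= 0")
    A = exchange_matrix(p["k_intra"], p["k_boundary"], p["v_surround"])

    n_pre, n_post, dt = int(p["n_pre"]), int(p["n_post"]), float(p["dt"])
    t_post = np.arange(1, n_post + 1) * dt
    x0 = np.array([1.0 - p["bleach_depth"], 1.0, 1.0])
    if n_post > 0:
        sol = solve_ivp(lambda t, x: A @ x, (0.0, t_post[-1]), x0,
                        t_eval=t_post, rtol=1e-10, atol=1e-12,
                        method="DOP853")
        post = sol.y
    else:
        post = np.empty((3, 0))

    time = np.arange(n_pre + n_post) * dt
    clean_b = np.concatenate([np.ones(n_pre), post[0]])
    clean_n = np.concatenate([np.ones(n_pre), post[1]])

    rng = _rng(seed, "gen_frap_traces")
    traces = []
    for _ in range(int(p["n_traces"])):
        scale = p["base_intensity"] * rng.uniform(0.8, 1.2) \
            if p["noise_sd"] > 0 else p["base_intensity"]
        b = scale * (clean_b + rng.normal(0, p["noise_sd"], len(time)))
        n = scale * (clean_n + rng.normal(0, p["noise_sd"], len(time)))
        traces.append(FrapTrace(time, np.clip(b, 0, None),
                                np.clip(n, 0, None), n_pre))
    truth = {"k_intra": p["k_intra"], "k_boundary": p["k_boundary"],
             "bleach_depth": p["bleach_depth"],
             "v_surround": p["v_surround"]}
    return FrapTraceSet(traces, condition=str(p["condition"]), truth=truth,
                        provenance=_provenance("gen_frap_traces", p, seed))


def gen_nucleus_image(params: Mapping | None = None,
                      seed: int = 0) -> NucleusImage:
    """Elliptical nucleus with bright, non-overlapping chromocenter foci.

    The DAPI channel is ``background`` outside the nucleus,
    ``nucleus_level`` inside, and ``focus_contrast * nucleus_level``
    inside each focus, plus Gaussian read noise.  Truth masks (nucleus and
    focus label map) are recorded.  Foci are packed by rejection sampling;
    an impossible packing raises after bounded retries.
    """
    p = {"shape": (128, 128), "n_foci": 6, "focus_radius": 6.0,
         "focus_contrast": 4.0, "background": 10.0, "nucleus_level": 100.0,
         "noise_sd": 2.0, "max_tries": 2000, "with_gfp": False,
         "pixel_size": 0.1}
    p.update(params or {})
    shape = tuple(int(s) for s in p["shape"])
    if len(shape) not in (2, 3):
        raise ValueError("shape must be 2-D or 3-D")
    if p["n_foci"] < 0:
        raise ValueError("n_foci must be >= 0")
    r = float(p["focus_radius"])
    center = np.array(shape) / 2.0
    semi = np.array(shape) * 0.42  # nucleus half-axes in pixels
    if p["n_foci"] > 0 and (r >= semi).any():
        raise ValueError("focus radius does not fit inside the nucleus")

    grid = np.indices(shape, dtype=float)
    inside = np.sum(((grid - center.reshape(-1, *([1] * len(shape))))
                     / semi.reshape(-1, *([1] * len(shape)))) ** 2,
                    axis=0) <= 1.0

    rng = _rng(seed, "gen_nucleus_image")
    centers: list[np.ndarray] = []
    tries = 0
    while len(centers) < int(p["n_foci"]):
        tries += 1
        if tries > int(p["max_tries"]):
            raise RuntimeError("could not pack the requested foci")
        cand = center + (rng.random(len(shape)) * 2 - 1) * (semi - r - 1)
        # keep the focus fully inside the nuclear ellipse
        if np.sum(((cand - center) / (semi - r)) ** 2) > 1.0:
            continue
        if any(np.linalg.norm(cand - c) < 2 * r + 1 for c in centers):
            continue
        centers.append(cand)

    labels = np.zeros(shape, dtype=np.uint16)
    for i, c in enumerate(centers, start=1):
        d2 = np.sum((grid - c.reshape(-1, *([1] * len(shape)))) ** 2, axis=0)
        labels[d2 <= r * r] = i

    dapi = np.full(shape, float(p["background"]))
    dapi[inside] = float(p["nucleus_level"])
    dapi[labels > 0] = float(p["focus_contrast"]) * float(p["nucleus_level"])
    if p["noise_sd"] > 0:
        dapi = dapi + rng.normal(0, float(p["noise_sd"]), shape)
    channels = {"dapi": np.clip(dapi, 0, None)}
    if p["with_gfp"]:
        gfp = np.full(shape, float(p["background"]))
        gfp[inside] = 0.5 * float(p["nucleus_level"])
        gfp[labels > 0] = float(p["nucleus_level"])
        if p["noise_sd"] > 0:
            gfp = gfp + rng.normal(0, float(p["noise_sd"]), shape)
        channels["gfp"] = np.clip(gfp, 0, None)
    pixel_size = tuple([float(p["pixel_size"])] * len(shape))
    truth = {"nucleus_mask": inside, "focus_labels": labels,
             "n_foci": int(p["n_foci"])}
    prov = _provenance("gen_nucleus_image",
                       {**p, "shape": list(shape)}, seed)
    return NucleusImage(channels, pixel_size, truth=truth, provenance=prov)


def gen_standard_curve(slope: float, intercept: float,
                       levels: Sequence[float], noise_sd: float,
                       seed: int = 0) -> StandardCurve:
    """Readings = slope*level + intercept + Gaussian noise."""
    levels = np.asarray(levels, dtype=float)
    if len(np.unique(levels)) < 2:
        raise ValueError("need >= 2 distinct levels")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = _rng(seed, "gen_standard_curve")
    readings = slope * levels + intercept + rng.normal(0, noise_sd,
                                                       len(levels))
    prov = _provenance("gen_standard_curve",
                       {"slope": slope, "intercept": intercept,
                        "levels": levels.tolist(), "noise_sd": noise_sd},
                       seed)
    return StandardCurve(levels, readings, provenance=prov)
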