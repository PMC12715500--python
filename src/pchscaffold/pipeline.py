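"""Configuration, orchestration and reporting for the whole screen.

``run_pipeline`` wires the stages — synthetic-data generation, the
predictor-consensus scaffold screen, condensate partition proteomics,
image quantification and half-bleach analysis — into one reproducible
run: every artifact is written under a run directory together with the
fully-resolved configuration, its hash and the seed, and a fixed
(config, seed) pair reproduces every numeric output byte for byte.
"""
from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import frap as frap_mod
from . import imaging as imaging_mod
from . import proteomics as prot_mod
from . import screen as screen_mod
from . import synthio

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "runs/demo",
    "stages": {"simulate": True, "screen": True, "proteomics": True,
               "imaging": True, "frap": True},
    "simulate": {
        "n_proteins": 400,
        "compartment_mix": {
            "pericentric_heterochromatin": 0.08,
            "euchromatin": 0.05,
            "nucleolus": 0.04,
            "nucleus_speckle": 0.04,
            "histone_deacetylase": 0.05,
            "histone_acetylase": 0.05,
            "nurd": 0.03,
        },
        "n_planted_scaffolds": 30,
        "predictor_effect": 10.0,
        "n_published": 10,
        "dia": {
            "base_sd": 0.5,
            "baseline_mean": 20.0,
            "baseline_sd": 2.0,
            "dropout_midpoint": 16.0,
            "dropout_slope": 1.0,
            "replicates": 3,
            "pellet_enrichment": 2.0,
            "acetylase_exclusion": -6.0,
            "nurd_recruitment": 3.0,
        },
        "pch_proteome_extra": 40,
        "image": {"shape": [96, 96], "n_foci": 5, "focus_radius": 5.0,
                  "focus_contrast": 6.0, "noise_sd": 1.0, "n_images": 3},
        "image_3d": {"shape": [16, 64, 64], "n_foci": 4,
                     "focus_radius": 4.0, "focus_contrast": 6.0,
                     "noise_sd": 1.0},
        "frap": {"k_intra": 0.5, "k_boundary_condition": 0.02,
                 "k_boundary_control": 5.0, "bleach_depth": 0.8,
                 "noise_sd": 0.01, "n_pre": 9, "n_post": 130, "dt": 1.3,
                 "n_traces": 8},
        "standard_curve": {"slope": 120.0, "intercept": 40.0,
                           "levels": [1, 5, 10, 20, 30], "noise_sd": 5.0},
    },
    "screen": {"top_n": 60, "min_support": 2, "self_cut": 60,
               "partner_cut": 60},
    "proteomics": {"min_samples": 3, "min_reps": 2, "impute_width": 0.3,
                   "impute_shift": 1.8},
    "imaging": {"k_sd": 2.0, "min_area": 5, "k_classes": 7,
                "molecular_weight": 50000.0, "n_nuclei": 1000000,
                "nuclear_volume": 4.0e-13, "reference_tissue": "muscle"},
    "frap": {"alpha": 0.01, "conc_low": 15.0, "conc_high": 35.0},
}


def resolve_config(overrides: Mapping | None = None) -> dict:
    """Merge user overrides into the defaults, rejecting unknown keys."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)

    def merge(base: dict, extra: Mapping, path: str) -> None:
        for key, val in extra.items():
            here = f"{path}.{key}" if path else str(key)
            if key not in base:
                # leaf mappings with free-form keys are replaced wholesale
                raise KeyError(f"unknown config key: {here}")
            if isinstance(base[key], dict) and isinstance(val, Mapping) \
                    and key not in ("compartment_mix",):
                merge(base[key], val, here)
            else:
                base[key] = copy.deepcopy(val) if isinstance(val, (dict, list)) \
                    else val

    if overrides:
        merge(cfg, overrides, "")
    return cfg


def load_config(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return resolve_config(data)


def config_hash(cfg: Mapping) -> str:
    # outdir is excluded so runs of one configuration hash identically
    # wherever their outputs land
    hashed = {k: v for k, v in cfg.items() if k != "outdir"}
    blob = json.dumps(hashed, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_json(path: Path, payload: dict, stamp: dict) -> None:
    with open(path, "w") as fh:
        json.dump({**stamp, **payload}, fh, indent=2, sort_keys=True)


def _tsv_stamp(path: Path, stamp: dict) -> None:
    """Prepend the run stamp as a comment line readers skip."""
    text = path.read_text()
    path.write_text(f"# config={stamp['config_hash']} "
                    f"seed={stamp['seed']}\n" + text)


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(cfg: dict, seed: int, outdir: Path, stamp: dict) -> dict:
    sim = cfg["simulate"]
    ann = synthio.gen_annotations(sim["n_proteins"],
                                  sim["compartment_mix"], seed=seed)
    pch_truth = sorted(
        ann.ids_with_compartment("pericentric_heterochromatin"))
    rng = synthio._rng(seed, "pipeline/planting")
    n_plant = min(sim["n_planted_scaffolds"], len(pch_truth))
    planted = set(rng.choice(pch_truth, size=n_plant, replace=False)) \
        if n_plant else set()
    published = set(rng.choice(sorted(planted),
                               size=min(sim["n_published"], len(planted)),
                               replace=False)) if planted else set()

    predictors = synthio.gen_predictor_scores(ann, planted,
                                              sim["predictor_effect"],
                                              seed=seed)

    d = sim["dia"]
    reps = int(d["replicates"])
    design = [("Nuclei", reps), ("HC", reps), ("HC_S", reps),
              ("HC_P", reps), ("HC_MBD2_S", reps), ("HC_MBD2_P", reps)]
    effects = {
        ("pericentric_heterochromatin", "HC_P"): d["pellet_enrichment"],
        ("pericentric_heterochromatin", "HC_MBD2_P"): d["pellet_enrichment"],
        ("histone_deacetylase", "HC_P"): d["pellet_enrichment"],
        ("histone_deacetylase", "HC_MBD2_P"): d["pellet_enrichment"],
        ("histone_acetylase", "HC_P"): d["pellet_enrichment"],
        ("histone_acetylase", "HC_MBD2_P"): d["acetylase_exclusion"],
        ("nurd", "HC_MBD2_P"): d["nurd_recruitment"],
    }
    matrix = synthio.gen_dia_experiment(
        ann, design,
        params={"base_sd": d["base_sd"],
                "baseline_mean": d["baseline_mean"],
                "baseline_sd": d["baseline_sd"],
                "dropout_midpoint": d["dropout_midpoint"],
                "dropout_slope": d["dropout_slope"],
                "enrichment_effects": effects},
        seed=seed)

    # stand-in for the external PCH proteome: the ground-truth PCH ids
    # plus a sample of other detected proteins
    others = sorted(set(ann.ids) - set(pch_truth))
    extra = set(rng.choice(others,
                           size=min(sim["pch_proteome_extra"], len(others)),
                           replace=False))
    pch_proteome = set(pch_truth) | extra

    imgs = [synthio.gen_nucleus_image({**sim["image"],
                                       "shape": tuple(sim["image"]["shape"])},
                                      seed=seed + i)
            for i in range(int(sim["image"]["n_images"]))]
    img3d = synthio.gen_nucleus_image(
        {**sim["image_3d"], "shape": tuple(sim["image_3d"]["shape"])},
        seed=seed + 1000)

    f = sim["frap"]
    frap_condition = synthio.gen_frap_traces(
        {**{k: f[k] for k in ("k_intra", "bleach_depth", "noise_sd",
                              "n_pre", "n_post", "dt", "n_traces")},
         "k_boundary": f["k_boundary_condition"], "condition": "condensate"},
        seed=seed)
    frap_control = synthio.gen_frap_traces(
        {**{k: f[k] for k in ("k_intra", "bleach_depth", "noise_sd",
                              "n_pre", "n_post", "dt", "n_traces")},
         "k_boundary": f["k_boundary_control"], "condition": "free_solution"},
        seed=seed + 1)

    sc = sim["standard_curve"]
    curve = synthio.gen_standard_curve(sc["slope"], sc["intercept"],
                                       sc["levels"], sc["noise_sd"],
                                       seed=seed)

    # persist the on-disk forms
    ann.to_tsv(outdir / "annotations.tsv")
    _tsv_stamp(outdir / "annotations.tsv", stamp)
    for ps in predictors:
        p = outdir / f"predictor_{ps.predictor_name}.tsv"
        ps.to_tsv(p)
        _tsv_stamp(p, stamp)
    matrix.to_tsv(outdir / "intensities_raw.tsv")
    _tsv_stamp(outdir / "intensities_raw.tsv", stamp)
    pd.DataFrame({"protein_id": sorted(pch_proteome)}).to_csv(
        outdir / "pch_proteome.tsv", sep="\t", index=False)
    _tsv_stamp(outdir / "pch_proteome.tsv", stamp)
    frap_condition.to_csv(outdir / "frap_condensate.csv")
    frap_control.to_csv(outdir / "frap_free_solution.csv")
    curve.to_csv(outdir / "standard_curve.csv")
    for i, im in enumerate(imgs):
        im.to_tiff(outdir / f"nucleus_2d_{i}.tiff")
    img3d.to_tiff(outdir / "nucleus_3d.tiff")

    return {"annotations": ann, "predictors": predictors, "matrix": matrix,
            "planted": planted, "published": published,
            "pch_proteome": pch_proteome, "images": imgs,
            "image_3d": img3d, "frap_condition": frap_condition,
            "frap_control": frap_control, "curve": curve}


def _stage_screen(cfg: dict, data: dict, outdir: Path, stamp: dict) -> dict:
    sc = cfg["screen"]
    preds = {p.predictor_name: p for p in data["predictors"]}
    n = int(sc["top_n"])
    drllps = screen_mod.top_n_candidates(preds["drllps_list"], n)
    psap = screen_mod.top_n_candidates(preds["psap"], n)
    self_top = screen_mod.top_n_candidates(preds["phasepred_self"],
                                           int(sc["self_cut"]))
    partner_top = screen_mod.top_n_candidates(preds["phasepred_partner"],
                                              int(sc["partner_cut"]))
    phasepred = self_top | partner_top
    per_predictor = {"drllps": drllps, "psap": psap,
                     "phasepred": phasepred}
    consensus = screen_mod.consensus_vote(
        [drllps, psap, phasepred], min_support=int(sc["min_support"]))

    catalog = screen_mod.build_catalog(consensus, per_predictor,
                                       data["published"],
                                       min_support=int(sc["min_support"]))
    catalog = screen_mod.filter_nuclear(catalog, data["annotations"])
    catalog = screen_mod.classify_compartments(catalog, data["annotations"])
    modes = screen_mod.classify_assembly(
        preds["phasepred_self"].entries, preds["phasepred_partner"].entries,
        self_cut=int(sc["self_cut"]), partner_cut=int(sc["partner_cut"]))
    catalog = screen_mod.apply_assembly_modes(catalog, modes)

    pch_pred = catalog.with_compartment("pericentric_heterochromatin")
    hc_p = prot_mod.replicate_presence(data["matrix"], "HC_P",
                                       cfg["proteomics"]["min_reps"])
    candidates, venn = screen_mod.triple_intersect(pch_pred, hc_p,
                                                   data["pch_proteome"])

    catalog.to_tsv(outdir / "scaffold_catalog.tsv")
    _tsv_stamp(outdir / "scaffold_catalog.tsv", stamp)
    venn.to_json(outdir / "venn_counts.json")
    _write_json(outdir / "pch_candidates.json",
                {"candidates": sorted(candidates),
                 "n_candidates": len(candidates)}, stamp)
    planted = data["planted"]
    recall = (len(candidates & planted) / len(planted)) if planted else None
    return {"catalog": catalog, "candidates": candidates, "venn": venn,
            "consensus": consensus, "pch_pred": pch_pred, "hc_p": hc_p,
            "planted_recall": recall}


def _stage_proteomics(cfg: dict, data: dict, outdir: Path,
                      stamp: dict, seed: int) -> dict:
    pc = cfg["proteomics"]
    matrix = prot_mod.detection_filter(data["matrix"],
                                       int(pc["min_samples"]))
    log2 = prot_mod.log2_median_normalize(matrix)
    imputed = prot_mod.impute_downshift(log2, width=pc["impute_width"],
                                        shift=pc["impute_shift"], seed=seed)

    min_reps = int(pc["min_reps"])
    hc = prot_mod.replicate_presence(matrix, "HC", min_reps)
    hc_s = prot_mod.replicate_presence(matrix, "HC_S", min_reps)
    hc_p = prot_mod.replicate_presence(matrix, "HC_P", min_reps)
    partition = prot_mod.partition_classify(hc | hc_s | hc_p, hc_s, hc_p)

    mbd2_p = prot_mod.replicate_presence(matrix, "HC_MBD2_P", min_reps)
    shift = prot_mod.composition_shift(hc_p, mbd2_p)

    ann = data["annotations"]
    classes = screen_mod.keyword_classes(ann)
    summaries = {}
    for label in ("histone_acetylase", "histone_deacetylase"):
        summaries[label] = prot_mod.functional_partition_summary(
            classes[label], hc_p, shift)
    domain_fracs = {}
    for name, ids in (("recruited", shift.recruited),
                      ("excluded", shift.excluded)):
        domain_fracs[name] = {
            dom: (prot_mod.domain_fraction(ids, ann, dom) if ids else None)
            for dom in ("cc", "znf")}

    nurd_ids = sorted(classes["nurd"] & set(imputed.proteins))
    diff = prot_mod.differential_abundance(imputed, "HC_P", "HC_MBD2_P",
                                           nurd_ids) if nurd_ids else \
        pd.DataFrame(columns=["protein_id", "log2_fc", "p", "significant",
                              "flagged"])

    imputed.to_tsv(outdir / "intensities_log2_imputed.tsv")
    _tsv_stamp(outdir / "intensities_log2_imputed.tsv", stamp)
    diff.to_csv(outdir / "nurd_differential.tsv", sep="\t", index=False)
    _tsv_stamp(outdir / "nurd_differential.tsv", stamp)
    _write_json(outdir / "partition.json", partition.to_dict(), stamp)
    _write_json(outdir / "composition_shift.json",
                {**shift.to_dict(), "functional_summaries": summaries,
                 "domain_fractions": domain_fracs}, stamp)
    return {"matrix_imputed": imputed, "partition": partition,
            "shift": shift, "summaries": summaries,
            "domain_fractions": domain_fracs, "nurd_differential": diff}


def _stage_imaging(cfg: dict, data: dict, outdir: Path, stamp: dict,
                   seed: int) -> dict:
    im = cfg["imaging"]
    rows = []
    for i, img in enumerate(data["images"]):
        dapi = img.channels["dapi"]
        mask = imaging_mod.segment_nucleus(dapi)
        foci = imaging_mod.segment_pch(dapi, mask,
                                       min_area=int(im["min_area"]),
                                       k_sd=im["k_sd"])
        quant = imaging_mod.quantify_nucleus(img.channels, foci, mask)
        rows.append({"image": i, "s_n": quant.s_n, "i_n": quant.i_n,
                     "n_foci": quant.n,
                     "pct_dapi_in_pch": quant.pct_in_pch["dapi"]})
    table = pd.DataFrame(rows)

    img3d = data["image_3d"]
    mask3d = imaging_mod.segment_nucleus(img3d.channels["dapi"])
    profile = imaging_mod.compaction_classify(img3d.channels["dapi"],
                                              mask3d,
                                              k=int(im["k_classes"]),
                                              seed=seed)

    curve = imaging_mod.fit_standard_curve(data["curve"])
    conc = imaging_mod.abundance_from_blot(
        band_intensity=float(curve.slope * 10 + curve.intercept),
        curve=curve, n_nuclei=int(im["n_nuclei"]),
        molecular_weight=im["molecular_weight"],
        nuclear_volume=im["nuclear_volume"])
    expr = imaging_mod.assign_expression_class(conc)

    ann = data["annotations"]
    ref = im["reference_tissue"]
    ppm = ann.tissue_ppm(ann.ids[0]) if ann.ppm_columns else {}
    tissue = imaging_mod.tissue_scale(conc, ref, ppm) if ppm else None

    table.to_csv(outdir / "imaging_quant.tsv", sep="\t", index=False)
    _tsv_stamp(outdir / "imaging_quant.tsv", stamp)
    _write_json(outdir / "imaging_summary.json", {
        "per_image": rows,
        "compaction_pct_intensity": profile.pct_intensity.tolist(),
        "standard_curve": {"slope": curve.slope,
                           "intercept": curve.intercept, "r2": curve.r2},
        "blot_concentration_uM": conc,
        "expression_class": expr.label,
        "tissue_scaling": tissue,
    }, stamp)
    return {"quant_table": table, "compaction": profile, "curve": curve,
            "blot_concentration": conc, "expression_class": expr,
            "tissue_scaling": tissue}


def _stage_frap(cfg: dict, data: dict, outdir: Path, stamp: dict) -> dict:
    fc = cfg["frap"]
    dips = {}
    for name, ts in (("condensate", data["frap_condition"]),
                     ("free_solution", data["frap_control"])):
        dips[name] = [frap_mod.compute_dip(
            frap_mod.normalize_halves(tr)).dip for tr in ts.traces]
    call = frap_mod.barrier_call(dips["condensate"], dips["free_solution"],
                                 alpha=fc["alpha"])

    norm = [frap_mod.normalize_halves(tr)
            for tr in data["frap_condition"].traces]
    flip_like = [tr.nonbleached / tr.nonbleached[0] for tr in norm]
    flip = frap_mod.flip_summary(flip_like)

    _write_json(outdir / "frap_summary.json", {
        "dips": dips, "barrier_call": call,
        "flip_mean_final": float(flip["mean"][-1]),
        "flip_ci_half_final": float(flip["ci_half_width"][-1]),
    }, stamp)
    return {"dips": dips, "barrier_call": call, "flip": flip}


# ---------------------------------------------------------------------------
# driver


def run_pipeline(config: Mapping | None = None,
                 seed: int | None = None,
                 outdir: str | Path | None = None) -> dict:
    """Run the toggled stages and write the report bundle.

    Returns a dict of in-memory stage results; all artifacts are written
    under the run directory with the resolved config, its hash and seed.
    """
    cfg = resolve_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    if outdir is not None:
        cfg["outdir"] = str(outdir)
    seed = int(cfg["seed"])
    out = Path(cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config_hash(cfg), "seed": seed}
    with open(out / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump({**cfg, "config_hash": stamp["config_hash"]}, fh,
                       sort_keys=True)

    results: dict = {"config": cfg, "stamp": stamp}
    stages = cfg["stages"]
    if not stages["simulate"]:
        raise ValueError("synthetic mode is the only input source; "
                         "enable the simulate stage")
    data = _stage_simulate(cfg, seed, out, stamp)
    results["simulate"] = data
    if stages["screen"]:
        results["screen"] = _stage_screen(cfg, data, out, stamp)
    if stages["proteomics"]:
        results["proteomics"] = _stage_proteomics(cfg, data, out, stamp,
                                                  seed)
    if stages["imaging"]:
        results["imaging"] = _stage_imaging(cfg, data, out, stamp, seed)
    if stages["frap"]:
        results["frap"] = _stage_frap(cfg, data, out, stamp)

    _write_report(results, out, stamp)
    return results


def _write_report(results: dict, outdir: Path, stamp: dict) -> None:
    lines = [f"pipeline run (config {stamp['config_hash']}, "
             f"seed {stamp['seed']})", ""]
    payload: dict = {}
    if "screen" in results:
        sc = results["screen"]
        payload["screen"] = {
            "n_consensus": len(sc["consensus"]),
            "n_catalog": len(sc["catalog"].ids),
            "n_pch_predicted": len(sc["pch_pred"]),
            "n_candidates": len(sc["candidates"]),
            "planted_recall": sc["planted_recall"],
            "venn": sc["venn"].to_dict(),
        }
        lines += [f"consensus scaffolds: {len(sc['consensus'])}",
                  f"catalog entries (nuclear): {len(sc['catalog'].ids)}",
                  f"PCH-predicted scaffolds: {len(sc['pch_pred'])}",
                  f"triple-intersection candidates: "
                  f"{len(sc['candidates'])}",
                  f"planted-scaffold recall: {sc['planted_recall']}"]
    if "proteomics" in results:
        pr = results["proteomics"]
        payload["proteomics"] = {
            "partition": {k: v for k, v in pr["partition"].to_dict().items()
                          if k.startswith("n_")},
            "shift": {k: v for k, v in pr["shift"].to_dict().items()
                      if k.startswith("n_")},
            "functional_summaries": pr["summaries"],
        }
        d = pr["partition"].to_dict()
        lines += [f"partition P&S/P-only/S-only: {d['n_p_and_s']}/"
                  f"{d['n_p_only']}/{d['n_s_only']}"]
    if "imaging" in results:
        im = results["imaging"]
        payload["imaging"] = {
            "mean_pct_dapi_in_pch":
                float(im["quant_table"]["pct_dapi_in_pch"].mean()),
            "blot_concentration_uM": im["blot_concentration"],
            "expression_class": im["expression_class"].label,
        }
        lines += [f"mean %DAPI in PCH: "
                  f"{payload['imaging']['mean_pct_dapi_in_pch']:.1f}"]
    if "frap" in results:
        fr = results["frap"]
        payload["frap"] = {"barrier_call": fr["barrier_call"]}
        lines += [f"barrier: {fr['barrier_call']['barrier']} "
                  f"(p={fr['barrier_call']['p']:.3g})"]
    _write_json(outdir / "report.json", payload, stamp)
    (outdir / "report.txt").write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# table validation


def validate_tables(paths: list) -> list[dict]:
    """Schema/invariant diagnostics for on-disk tables.

    Returns one dict per violation with file, row (1-based data row where
    known) and message; an empty list means every table passed.
    """
    problems: list[dict] = []
    for path in paths:
        path = Path(path)
        try:
            df = pd.read_csv(path, sep="\t" if path.suffix == ".tsv"
                             else ",", comment="#",
                             keep_default_na=False,
                             na_values=[synthio.MISSING])
        except Exception as exc:  # unreadable file
            problems.append({"file": str(path), "row": None,
                             "message": f"unreadable: {exc}"})
            continue
        if "protein_id" in df.columns:
            dup = df["protein_id"].duplicated()
            for i in df.index[dup]:
                problems.append({"file": str(path), "row": int(i) + 1,
                                 "message": "duplicated protein_id "
                                            f"{df.loc[i, 'protein_id']!r}"})
        if "disorder_fraction" in df.columns:
            bad = ~df["disorder_fraction"].astype(float).between(0, 1)
            for i in df.index[bad]:
                problems.append({"file": str(path), "row": int(i) + 1,
                                 "message": "disorder_fraction outside "
                                            "[0, 1]"})
        value_cols = [c for c in df.columns if ".r" in c]
        for col in value_cols:
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = vals.notna() & (vals <= 0)
            for i in df.index[bad]:
                problems.append({"file": str(path), "row": int(i) + 1,
                                 "message": f"non-positive raw intensity "
                                            f"in {col}"})
    return problems
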