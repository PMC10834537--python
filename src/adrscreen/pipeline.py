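"""End-to-end orchestration of the multi-source signal-detection analysis.

Flow: per-disease registry screen -> label exclusion -> merge strata ->
SRS disproportionality validation -> intersection -> final signal table,
with a parallel laboratory screen annotated as supplementary evidence (it
corroborates but does not gate inclusion). Every stage writes TSV outputs
into its own subdirectory plus a JSON run manifest, and identical
(config, seed) reruns produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml

from . import simulate
from .datasets import EhrLabDataset, RegistryDataset, SrsDataset, VocabMappings
from .dispro import Disproportionality, DisproResults
from .lab import LabScreen, LabScreenResults, catalog_to_tsv, load_catalog
from .labels import LabelKnowledgeBase, filter_novel
from .registry import RegistryScreen, SignalResult, select_valid_cases

__all__ = ["FinalSignal", "intersect_signals", "run_pipeline", "PipelineResult"]

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


@dataclass(frozen=True)
class FinalSignal:
    """A drug--event pair surviving all selection stages.

    Present only when registry-significant, absent from the label knowledge
    base and significant in the SRS by any of PRR/ROR/IC; ``strata`` records
    the disease cohorts in which the registry evidence arose.
    """

    generic_drug: str
    preferred_term: str
    strata: tuple[str, ...]
    registry_evidence: tuple[SignalResult, ...]
    srs_evidence: Mapping[str, Any]
    metalab_evidence: Mapping[str, Any] | None = None


def intersect_signals(
    novel_by_stratum: Mapping[str, Sequence[SignalResult]],
    srs_annotations: pd.DataFrame,
    metalab: pd.DataFrame | None = None,
) -> list[FinalSignal]:
    """Intersect label-novel registry signals with SRS-significant pairs.

    ``srs_annotations`` is the output of
    :meth:`~adrscreen.dispro.DisproResults.annotate` for the union of novel
    pairs. Pairs novel in both strata appear once with both strata recorded.
    Laboratory evidence, when provided, is joined on (drug, preferred term).
    """
    sig_lookup = {
        (row.drug, row.term): row
        for row in srs_annotations.itertuples(index=False)
        if row.significant_any
    }
    lab_lookup: dict[tuple[str, str], dict] = {}
    if metalab is not None and len(metalab):
        for row in metalab.itertuples(index=False):
            if row.significant and row.preferred_term:
                lab_lookup[(row.generic_drug, row.preferred_term)] = row._asdict()

    merged: dict[tuple[str, str], dict] = {}
    for stratum in novel_by_stratum:
        for signal in novel_by_stratum[stratum]:
            key = (signal.generic_drug, signal.preferred_term)
            if key not in sig_lookup:
                continue
            entry = merged.setdefault(key, {"strata": [], "registry": []})
            if stratum not in entry["strata"]:
                entry["strata"].append(stratum)
            entry["registry"].append(signal)

    out = []
    for key in sorted(merged):
        drug, term = key
        entry = merged[key]
        srs_row = sig_lookup[key]
        out.append(
            FinalSignal(
                generic_drug=drug,
                preferred_term=term,
                strata=tuple(entry["strata"]),
                registry_evidence=tuple(entry["registry"]),
                srs_evidence=srs_row._asdict(),
                metalab_evidence=lab_lookup.get(key),
            )
        )
    return out


def _final_frame(finals: Sequence[FinalSignal]) -> pd.DataFrame:
    rows = []
    for f in finals:
        reg = {s.disease: s for s in f.registry_evidence}
        rows.append(
            dict(
                generic_drug=f.generic_drug,
                preferred_term=f.preferred_term,
                strata=",".join(f.strata),
                is_lab_abnormality=any(s.is_lab_abnormality for s in f.registry_evidence),
                registry_rr=";".join(
                    f"{d}:{reg[d].rr:.4g}" for d in sorted(reg)
                ),
                srs_fdr_prr=f.srs_evidence["fdr_prr"],
                srs_fdr_ror=f.srs_evidence["fdr_ror"],
                srs_fdr_ic=f.srs_evidence["fdr_ic"],
                metalab_significant=f.metalab_evidence is not None,
            )
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "generic_drug",
            "preferred_term",
            "strata",
            "is_lab_abnormality",
            "registry_rr",
            "srs_fdr_prr",
            "srs_fdr_ror",
            "srs_fdr_ic",
            "metalab_significant",
        ],
    )
    # group signals by drug, as in a final summary table
    return frame.sort_values(["generic_drug", "preferred_term"], kind="stable").reset_index(
        drop=True
    )


# --------------------------------------------------------------------------
# configuration and run driver
# --------------------------------------------------------------------------

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "data": {"mode": "demo"},
    "registry": {"alpha": 0.05, "min_count": 15, "point_estimate_only": False},
    "dispro": {"threshold": 0.05, "mc_draws": 5000},
    "metalab": {"window_days": 365, "comparator": "other_drugs"},
}


class PipelineConfigError(ValueError):
    """The run configuration does not match the documented schema."""


def _load_config(config: str | Path | Mapping[str, Any]) -> dict[str, Any]:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    if not isinstance(config, Mapping):
        raise PipelineConfigError("configuration must be a mapping")
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, value in config.items():
        if key not in merged:
            raise PipelineConfigError(f"unknown configuration section: {key!r}")
        if isinstance(merged[key], dict):
            if not isinstance(value, Mapping):
                raise PipelineConfigError(f"section {key!r} must be a mapping")
            unknown = set(value) - set(merged[key]) - {"paths"}
            if unknown:
                raise PipelineConfigError(f"unknown keys in section {key!r}: {sorted(unknown)}")
            merged[key].update(value)
        else:
            merged[key] = value
    mode = merged["data"].get("mode")
    if mode not in ("demo", "paths"):
        raise PipelineConfigError("data.mode must be 'demo' or 'paths'")
    if mode == "paths":
        required = {"registry_dir", "srs", "ehr_dir", "mappings_dir", "label_kb", "lab_catalog"}
        paths = merged["data"].get("paths") or {}
        missing = required - set(paths)
        if missing:
            raise PipelineConfigError(f"data.paths missing entries: {sorted(missing)}")
    return merged


def _hash_file(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()[:16]


@dataclass
class PipelineResult:
    """Artifacts and headline counts from one pipeline run."""

    out_dir: Path
    counts: dict[str, int]
    final_signals: list[FinalSignal]
    final_frame: pd.DataFrame


def run_pipeline(
    config: str | Path | Mapping[str, Any],
    out_dir: str | Path,
    seed: int | None = None,
) -> PipelineResult:
    """Run the full analysis described by a configuration mapping or file.

    Stage outputs land in numbered subdirectories of ``out_dir``; the
    manifest records the seed, configuration and content hashes of every
    written table. ``seed`` overrides the configured seed.
    """
    cfg = _load_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    run_seed = int(cfg["seed"])
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def stage_log(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    # ---- stage 0: data -------------------------------------------------
    data_dir = out / "00_data"
    if cfg["data"]["mode"] == "demo":
        bundle = simulate.generate_demo(run_seed)
        registry, srs, ehr = bundle.registry, bundle.srs, bundle.ehr
        mappings, kb, catalog = bundle.mappings, bundle.kb, bundle.catalog
        registry.to_tsv(data_dir / "registry")
        srs.to_tsv(data_dir / "srs" / "reports.tsv")
        ehr.to_tsv(data_dir / "ehr")
        mappings.to_tsv(data_dir / "mappings")
        kb.to_tsv(data_dir / "label_kb.tsv")
        catalog_to_tsv(catalog, data_dir / "lab_catalog.tsv")
        bundle.ground_truth.to_json(data_dir / "ground_truth.json")
    else:
        paths = cfg["data"]["paths"]
        registry = RegistryDataset.from_tsv(paths["registry_dir"])
        srs = SrsDataset.from_tsv(paths["srs"])
        ehr = EhrLabDataset.from_tsv(paths["ehr_dir"])
        mappings = VocabMappings.from_tsv(paths["mappings_dir"])
        kb = LabelKnowledgeBase.from_tsv(paths["label_kb"])
        catalog = load_catalog(paths["lab_catalog"])
    stage_log(
        f"data: {len(registry.patients)} patients, {len(registry.events)} events, "
        f"{len(registry.adr_reports)} ADR reports, {srs.reports['report_id'].nunique() if len(srs.reports) else 0} "
        f"SRS reports, {len(ehr.measurements)} lab measurements"
    )

    # ---- stage 1: registry screen per disease --------------------------
    reg_dir = out / "10_registry"
    reg_dir.mkdir(parents=True, exist_ok=True)
    cases = select_valid_cases(registry, mappings)
    screens: dict[str, Any] = {}
    counts: dict[str, int] = {}
    for disease in sorted(cases):
        model = RegistryScreen(
            cases[disease],
            alpha=float(cfg["registry"]["alpha"]),
            min_count=int(cfg["registry"]["min_count"]),
            point_estimate_only=bool(cfg["registry"]["point_estimate_only"]),
        )
        results = model.fit()
        screens[disease] = results
        results.frame.to_csv(
            reg_dir / f"signals_{disease}.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
        )
        counts[f"cases_{disease}"] = len(cases[disease])
        counts[f"significant_{disease}"] = int(results.frame["significant"].sum())
        stage_log(
            f"registry[{disease}]: {len(cases[disease])} cases -> "
            f"{len(results.frame)} pairs, {counts[f'significant_{disease}']} significant"
        )

    # ---- stage 2: label exclusion --------------------------------------
    novel_dir = out / "20_novel"
    novel_dir.mkdir(parents=True, exist_ok=True)
    novel_by_stratum: dict[str, list[SignalResult]] = {}
    for disease, results in screens.items():
        novel, excluded = filter_novel(results.signals, kb)
        novel_by_stratum[disease] = novel
        for name, part in (("novel", novel), ("excluded", excluded)):
            frame = pd.DataFrame(
                [
                    dict(
                        disease=s.disease,
                        generic_drug=s.generic_drug,
                        preferred_term=s.preferred_term,
                        a=s.a,
                        rr=s.rr,
                        ci_low=s.ci_low,
                        ci_high=s.ci_high,
                        is_lab_abnormality=s.is_lab_abnormality,
                    )
                    for s in part
                ]
            )
            frame.to_csv(
                novel_dir / f"{name}_{disease}.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
            )
        counts[f"novel_{disease}"] = len(novel)
        counts[f"label_excluded_{disease}"] = len(excluded)
        stage_log(
            f"label exclusion[{disease}]: {len(novel) + len(excluded)} significant -> "
            f"{len(excluded)} label-known, {len(novel)} novel"
        )

    # ---- stage 3: SRS disproportionality -------------------------------
    dispro_dir = out / "30_dispro"
    dispro_dir.mkdir(parents=True, exist_ok=True)
    model = Disproportionality.from_reports(
        srs,
        mappings,
        threshold=float(cfg["dispro"]["threshold"]),
        mc_draws=int(cfg["dispro"]["mc_draws"]),
    )
    dispro_results = model.fit(seed=simulate.child_rng(run_seed, "dispro_mc"))
    dispro_results.frame.to_csv(
        dispro_dir / "dispro_all_pairs.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )
    annotations_by_stratum: dict[str, pd.DataFrame] = {}
    union_pairs: list[tuple[str, str]] = []
    for disease, novel in sorted(novel_by_stratum.items()):
        pairs = [(s.generic_drug, s.preferred_term) for s in novel]
        annot = dispro_results.annotate(pairs)
        annotations_by_stratum[disease] = annot
        annot.to_csv(
            dispro_dir / f"candidates_{disease}.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
        )
        counts[f"srs_confirmed_{disease}"] = int(annot["significant_any"].sum())
        stage_log(
            f"dispro[{disease}]: {len(annot)} candidates -> "
            f"{counts[f'srs_confirmed_{disease}']} SRS-significant"
        )
        for pair in pairs:
            if pair not in union_pairs:
                union_pairs.append(pair)
    union_annot = dispro_results.annotate(union_pairs)

    # ---- stage 4: laboratory screen ------------------------------------
    metalab_dir = out / "40_metalab"
    metalab_dir.mkdir(parents=True, exist_ok=True)
    lab_results: LabScreenResults = LabScreen(
        ehr,
        catalog,
        window_days=float(cfg["metalab"]["window_days"]),
        comparator=str(cfg["metalab"]["comparator"]),
    ).fit()
    lab_results.frame.to_csv(
        metalab_dir / "lab_screen.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )
    counts["metalab_significant"] = int(lab_results.frame["significant"].sum())
    stage_log(
        f"metalab: {len(lab_results.frame)} (drug, signal) pairs -> "
        f"{counts['metalab_significant']} significant"
    )

    # ---- stage 5: intersection -----------------------------------------
    final_dir = out / "50_final"
    final_dir.mkdir(parents=True, exist_ok=True)
    finals = intersect_signals(novel_by_stratum, union_annot, metalab=lab_results.frame)
    final_frame = _final_frame(finals)
    final_frame.to_csv(
        final_dir / "final_signals.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )
    counts["final_signals"] = len(finals)
    stage_log(f"final: {len(finals)} novel signal candidates after intersection")

    # ---- manifest and log ----------------------------------------------
    tables = sorted(p for p in out.rglob("*.tsv"))
    manifest = {
        "seed": run_seed,
        "config": cfg,
        "counts": counts,
        "tables": {str(p.relative_to(out)): _hash_file(p) for p in tables},
        "version": _package_version(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return PipelineResult(out_dir=out, counts=counts, final_signals=finals, final_frame=final_frame)


def _package_version() -> str:
    from . import __version__

    return __version__
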