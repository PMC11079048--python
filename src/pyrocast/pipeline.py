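"""End-to-end orchestration: predict -> threshold -> match -> classify -> report.

The pipeline runs every flavour through reaction enumeration and ranking,
matches the ranked products against that flavour's thresholded EI-MS
spectrum, attaches GHS/Cramer classifications, and collates per-flavour
risk reports plus aggregate statistics.  Per-flavour failures are
isolated (logged and recorded, the run continues); outputs are written
in a pinned order so re-running an identical configuration reproduces
byte-identical files.

The recount helpers at the bottom recompute headline statistics (total
and discrete product counts, match counts and rank shares, category
tallies, mean molecular weight) from prediction/match/classification
tables in the pipeline's CSV/XLSX exchange formats.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import chem_core, diversity_space, hazard_profile, ms_spectra, \
    nn_ms_matching, pyrolysis_enum
from .chem_core import Molecule
from .hazard_profile import FlavourRiskReport
from .nn_ms_matching import MatchStatistics
from .synthetic_data import SyntheticCase

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
    "run_cases",
    "predictions_frame",
    "matches_frame",
    "read_supplementary_table",
    "recount_predictions",
    "recount_matches",
    "recount_ghs",
    "recount_flavour_mw",
]


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of the workflow; the defaults are the study settings
    (25 ranked predictions, up to 5 bond changes over at most 16
    break sites, 5 % abundance threshold, 1.0 Da mass-key offset)."""

    flavours_path: str = ""
    spectra_dir: str = ""
    ghs_path: str | None = None
    cramer_path: str | None = None
    output_dir: str | None = None
    top_k: int = pyrolysis_enum.DEFAULT_TOP_K
    max_changes: int = pyrolysis_enum.DEFAULT_MAX_CHANGES
    max_break_sites: int = pyrolysis_enum.DEFAULT_MAX_BREAK_SITES
    threshold: float = ms_spectra.DEFAULT_THRESHOLD
    mass_offset: float = nn_ms_matching.DEFAULT_MASS_OFFSET
    allow_radicals: bool = False
    seed: int = 0

    @classmethod
    def from_json(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = json.load(fh)
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


@dataclass
class PipelineResult:
    reports: list[FlavourRiskReport]
    statistics: MatchStatistics | None
    category_tally: dict[str, int]
    provenance: dict[str, list[str]]
    failed_flavours: list[str] = field(default_factory=list)
    stage_counts: dict[str, int] = field(default_factory=dict)


def _process_flavour(flavour: Molecule, flavour_id: str, spectrum,
                     ghs_lookup, cramer_lookup, cfg: PipelineConfig):
    candidates = pyrolysis_enum.enumerate_candidate_reactions(
        flavour, max_changes=cfg.max_changes,
        max_break_sites=cfg.max_break_sites,
        allow_radicals=cfg.allow_radicals)
    predictions = pyrolysis_enum.score_and_rank(
        flavour, candidates, top_k=cfg.top_k)
    spec = ms_spectra.apply_threshold(spectrum, cfg.threshold)
    matchset = nn_ms_matching.match_flavour(
        flavour, flavour_id, predictions, spec, offset=cfg.mass_offset)
    return hazard_profile.build_flavour_report(
        flavour, flavour_id, predictions, matchset, ghs_lookup, cramer_lookup)


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """File-based run: read flavours/spectra/lookups, write all outputs."""
    flavours_path = Path(cfg.flavours_path)
    if flavours_path.suffix == ".csv":
        flavours = chem_core.read_smiles_csv(flavours_path)
    else:
        flavours = chem_core.read_smiles_file(flavours_path)
    if not flavours:
        raise ValueError(f"no flavours found in {cfg.flavours_path}")
    ghs_lookup = hazard_profile.load_ghs_lookup(cfg.ghs_path) \
        if cfg.ghs_path else (lambda key: None)
    cramer_lookup = hazard_profile.load_cramer_lookup(cfg.cramer_path) \
        if cfg.cramer_path else None

    reports: list[FlavourRiskReport] = []
    failed: list[str] = []
    for name, mol in flavours:
        try:
            spec_path = Path(cfg.spectra_dir) / f"{name}.jdx"
            spectrum = ms_spectra.parse_jcamp(spec_path.read_text())
            reports.append(_process_flavour(
                mol, name, spectrum, ghs_lookup, cramer_lookup, cfg))
        except Exception as exc:
            logger.error("flavour %s failed: %s", name, exc)
            failed.append(name)
    result = _collate(reports, failed, cfg)
    if cfg.output_dir:
        write_outputs(result, cfg)
    return result


def run_cases(cases: list[SyntheticCase], cfg: PipelineConfig | None = None) -> PipelineResult:
    """In-memory run over synthetic cases (their predictions are reused)."""
    cfg = cfg or PipelineConfig()
    reports: list[FlavourRiskReport] = []
    failed: list[str] = []
    for case in cases:
        try:
            ghs_lookup = hazard_profile.load_ghs_lookup(case.hazard_table)
            cramer_lookup = hazard_profile.load_cramer_lookup(case.cramer_table)
            spec = ms_spectra.apply_threshold(case.spectrum, cfg.threshold)
            matchset = nn_ms_matching.match_flavour(
                case.flavour, case.flavour_id, list(case.predictions), spec,
                offset=cfg.mass_offset)
            reports.append(hazard_profile.build_flavour_report(
                case.flavour, case.flavour_id, list(case.predictions),
                matchset, ghs_lookup, cramer_lookup))
        except Exception as exc:
            logger.error("case %s failed: %s", case.flavour_id, exc)
            failed.append(case.flavour_id)
    return _collate(reports, failed, cfg)


def _collate(reports, failed, cfg: PipelineConfig) -> PipelineResult:
    matchsets = [r.matchset for r in reports]
    stats = nn_ms_matching.match_statistics(matchsets, top_k=cfg.top_k) \
        if matchsets else None
    tally = hazard_profile.category_tally(reports)
    provenance = nn_ms_matching.product_provenance_index(matchsets)
    n_predictions = sum(len(r.predictions) for r in reports)
    n_records = sum(len(r.matchset.records) for r in reports)
    n_discrete = sum(r.matchset.n_discrete for r in reports)
    counts = {
        "flavours": len(reports),
        "failed": len(failed),
        "predictions": n_predictions,
        "match_records": n_records,
        "discrete_matches": n_discrete,
    }
    for stage, n in counts.items():
        logger.info("pipeline stage %s: %d", stage, n)
    return PipelineResult(reports=reports, statistics=stats,
                          category_tally=tally, provenance=provenance,
                          failed_flavours=failed, stage_counts=counts)


# ---------------------------------------------------------------------------
# tabular views and writers

def predictions_frame(reports: list[FlavourRiskReport]) -> pd.DataFrame:
    """One row per predicted product: flavour, rank, score, product, edits."""
    rows = []
    for rep in reports:
        for pred in rep.predictions:
            for product in pred.products:
                rows.append({
                    "flavour_name": rep.flavour_id,
                    "flavour_smiles": rep.flavour_smiles,
                    "rank": pred.rank,
                    "score": pred.score,
                    "product_smiles": product.canonical_smiles,
                    "edit_summary": pred.edit_set.summary(),
                })
    return pd.DataFrame(rows, columns=["flavour_name", "flavour_smiles", "rank",
                                       "score", "product_smiles", "edit_summary"])


def matches_frame(reports: list[FlavourRiskReport]) -> pd.DataFrame:
    rows = [
        {"flavour_id": rep.flavour_id,
         "product_smiles": r.product.canonical_smiles,
         "nn_rank": r.nn_rank,
         "mass_key": r.product_mass_key,
         "matched_mz": r.matched_mz}
        for rep in reports for r in rep.matchset.records
    ]
    return pd.DataFrame(rows, columns=["flavour_id", "product_smiles", "nn_rank",
                                       "mass_key", "matched_mz"])


def write_outputs(result: PipelineResult, cfg: PipelineConfig) -> None:
    out = Path(cfg.output_dir)
    (out / "reports").mkdir(parents=True, exist_ok=True)
    predictions_frame(result.reports).to_csv(out / "predictions.csv", index=False)
    matches_frame(result.reports).to_csv(out / "matches.csv", index=False)
    pd.DataFrame(
        [{"flavour_id": r.flavour_id,
          "n_predictions": len(r.predictions),
          "n_discrete_matches": r.matchset.n_discrete,
          **{f"n_{k}": v for k, v in r.category_counts.items()},
          "inhalation_codes": ";".join(
              sorted({c for codes in r.inhalation_statements.values()
                      for c in codes}))}
         for r in result.reports]
    ).to_csv(out / "categories.csv", index=False)
    if result.statistics is not None:
        pd.DataFrame(
            sorted(result.statistics.rank_histogram.items()),
            columns=["rank", "n_matches"],
        ).to_csv(out / "rank_histogram.csv", index=False)
    for rep in result.reports:
        with open(out / "reports" / f"{rep.flavour_id}.json", "w") as fh:
            json.dump(rep.to_dict(), fh, indent=1, sort_keys=True)
    summary = {
        "stage_counts": result.stage_counts,
        "category_tally": result.category_tally,
        "failed_flavours": result.failed_flavours,
    }
    if result.statistics is not None:
        s = result.statistics
        summary["match_statistics"] = {
            "n_flavours": s.n_flavours,
            "mean_discrete_matches_per_flavour": s.mean_discrete_matches_per_flavour,
            "frac_at_least_one": s.frac_at_least_one,
            "frac_more_than_one": s.frac_more_than_one,
            "rank1_share": s.rank1_share,
            "top5_share": s.top5_share,
            "bottom5_share": s.bottom5_share,
        }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    # chemical-space export over flavours + discrete matched products
    mols: list[Molecule] = []
    ids: list[str] = []
    seen: set[str] = set()
    for rep in result.reports:
        if rep.flavour_smiles not in seen:
            seen.add(rep.flavour_smiles)
            mols.append(chem_core.parse_molecule(rep.flavour_smiles))
            ids.append(rep.flavour_id)
    for smi in sorted({s for rep in result.reports
                       for s in rep.matchset.discrete_products} - seen):
        mols.append(chem_core.parse_molecule(smi))
        ids.append(smi)
    if len(mols) >= 3:
        matrix = diversity_space.build_descriptor_matrix(mols, ids)
        matrix.to_csv(out / "descriptor_matrix.csv")
        pca = diversity_space.pca_project(matrix)
        pca.coordinates.to_csv(out / "pca_coordinates.csv")
        pd.DataFrame({
            "component": [f"PC{i+1}" for i in range(len(pca.variance_ratios))],
            "variance_ratio": pca.variance_ratios,
        }).to_csv(out / "pca_variance.csv", index=False)


# ---------------------------------------------------------------------------
# recount: headline statistics from exchange tables

def read_supplementary_table(path) -> pd.DataFrame:
    """Read a prediction/match/classification table (CSV or XLSX)."""
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        return pd.read_excel(path)
    return pd.read_csv(path)


def _col(df: pd.DataFrame, *names: str) -> str:
    lower = {c.lower(): c for c in df.columns}
    for name in names:
        if name in lower:
            return lower[name]
    raise ValueError(f"table lacks a column named one of {names}; "
                     f"has {list(df.columns)}")


def recount_predictions(df: pd.DataFrame) -> dict:
    """Totals over a predictions table (one row per predicted product)."""
    flavour = _col(df, "flavour_name", "flavour", "flavour_id")
    product = _col(df, "product_smiles", "product")
    per_flavour_discrete = df.groupby(flavour)[product].nunique()
    discrete = df.drop_duplicates([flavour, product])
    return {
        "n_flavours": int(df[flavour].nunique()),
        "total_products": int(len(df)),
        "discrete_products": int(per_flavour_discrete.sum()),
        "mean_discrete_products_per_flavour": float(per_flavour_discrete.mean()),
        "top_products": {
            str(k): int(v)
            for k, v in discrete[product].value_counts().head(20).items()
        },
    }


def recount_matches(df: pd.DataFrame, n_flavours: int | None = None,
                    top_k: int = pyrolysis_enum.DEFAULT_TOP_K) -> dict:
    """Match totals and rank shares from a match-records table."""
    flavour = _col(df, "flavour_id", "flavour", "flavour_name")
    product = _col(df, "product_smiles", "product")
    rank = _col(df, "nn_rank", "rank")
    if n_flavours is None:
        n_flavours = int(df[flavour].nunique())
    per_flavour = df.groupby(flavour)[product].nunique()
    counts = per_flavour.reindex(
        per_flavour.index, fill_value=0) if n_flavours == len(per_flavour) \
        else per_flavour
    n_with_match = int((counts >= 1).sum())
    n_more_than_one = int((counts > 1).sum())
    hist = df[rank].value_counts().sort_index()
    total = int(hist.sum())
    discrete = df.drop_duplicates([flavour, product])
    return {
        "discrete_matches": int(per_flavour.sum()),
        "mean_matches_per_flavour": float(per_flavour.sum() / n_flavours),
        "frac_at_least_one": n_with_match / n_flavours,
        "frac_more_than_one": n_more_than_one / n_flavours,
        "rank1_share": float(hist.get(1, 0) / total) if total else 0.0,
        "top5_share": float(hist.reindex(range(1, 6), fill_value=0).sum() / total)
        if total else 0.0,
        "bottom5_share": float(
            hist.reindex(range(top_k - 4, top_k + 1), fill_value=0).sum() / total)
        if total else 0.0,
        "top_matched_products": {
            str(k): int(v)
            for k, v in discrete[product].value_counts().head(20).items()
        },
    }


def recount_ghs(df: pd.DataFrame) -> dict:
    """Category tallies from a classification table (one row per product)."""
    category = _col(df, "category", "ghs_category")
    tally = df[category].value_counts()
    return {str(k): int(v) for k, v in tally.items()}


def recount_flavour_mw(mols: list[Molecule]) -> dict:
    """Mean molecular weight of a flavour list, on both mass scales."""
    import numpy as np

    return {
        "mean_average_mw": float(np.mean([chem_core.average_mass(m) for m in mols])),
        "mean_monoisotopic_mw": float(np.mean([chem_core.exact_mass(m) for m in mols])),
        "n": len(mols),
    }
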