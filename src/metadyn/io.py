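"""File dialects, configuration and the end-to-end pipeline driver.

All tables are TSV by default (decimal point, UTF-8); every output file
starts with a ``#`` comment line recording the tool version and the
parameter values used, and readers skip such comments, so outputs round-trip.
Samples are keyed by explicit sample_id, never by column position.
"""

from __future__ import annotations

import json
import logging
import sys
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, chem, dynamics, fingerprint, steady_state

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineError",
    "DEFAULT_THRESHOLDS",
    "read_intensity_matrix",
    "read_sample_meta",
    "read_metabolite_table",
    "read_ion_list",
    "read_pathway_gmt",
    "read_config",
    "write_table",
    "run_pipeline",
    "write_fixture_bundle",
]

#: Reference analysis thresholds.
DEFAULT_THRESHOLDS = {
    "tolerance": 0.003,  # Da, ion annotation window
    "max_confluence": 0.80,
    "p_reliable": 0.001,
    "fc_cut": 1.0,  # |median max log2 FC|
    "p_cut": 1e-10,  # combined p
    "sd_cut": 1.5,  # cross-line SD of max log2 FC
    "q_cut": 0.001,  # pathway enrichment
}


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage {stage}] {message}")


def _read_table(path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, comment="#", **kwargs)


def read_intensity_matrix(path) -> pd.DataFrame:
    """Ions x samples matrix: first column the ion id/m-z, remaining
    columns sample intensities.  Empty cells become missing values, never
    zeros.  Duplicated sample columns or non-numeric cells are errors."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    with open(path) as fh:
        header = next(
            (ln for ln in fh if ln.strip() and not ln.startswith("#")), ""
        )
    cols = header.rstrip("\n").split(sep)[1:]
    dupes = sorted({c for c in cols if cols.count(c) > 1})
    if dupes:
        raise ValueError(f"duplicated sample columns: {dupes}")
    df = _read_table(path, index_col=0)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(
                f"non-numeric intensity at row {row!r}, column {col!r}"
            )
        df[col] = coerced
    return df


def read_sample_meta(path) -> pd.DataFrame:
    """Sample metadata table keyed by ``sample_id``."""
    df = _read_table(path)
    if "sample_id" not in df.columns:
        raise ValueError("metadata must contain a 'sample_id' column")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id values in metadata")
    return df.set_index("sample_id")


def read_metabolite_table(path) -> list[chem.MetaboliteRecord]:
    """Reference metabolites: TSV with id, name, formula, is_keto_acid,
    source columns."""
    df = _read_table(path)
    required = {"id", "name", "formula"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metabolite table missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        records.append(
            chem.MetaboliteRecord(
                id=str(row["id"]),
                name=str(row["name"]),
                formula=chem.parse_formula(str(row["formula"])),
                is_keto_acid=bool(row.get("is_keto_acid", False)),
                source=str(row.get("source", "")),
            )
        )
    return records


def read_ion_list(path) -> list[float]:
    """Measured ion m/z values: either one value per line or a table with
    an ``mz`` column."""
    path = Path(path)
    text = [
        ln.strip()
        for ln in path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not text:
        return []
    if "\t" in text[0] or "mz" in text[0].lower().split(","):
        df = _read_table(path)
        cols = {c.lower(): c for c in df.columns}
        if "mz" not in cols:
            raise ValueError("ion table has no 'mz' column")
        return [float(v) for v in df[cols["mz"]]]
    return [float(v) for v in text]


def read_pathway_gmt(path) -> list[fingerprint.PathwaySet]:
    """Standard GMT: pathway_id <TAB> description <TAB> member ids...

    Duplicate members within a set are deduplicated with a warning; a line
    with fewer than three fields is an error reported with its number.
    """
    sets = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"GMT line {lineno}: expected >= 3 tab-separated fields, "
                f"got {len(fields)}"
            )
        members = [f for f in fields[2:] if f]
        if len(members) != len(set(members)):
            warnings.warn(
                f"GMT line {lineno} ({fields[0]}): duplicate members "
                "deduplicated",
                stacklevel=2,
            )
        sets.append(
            fingerprint.PathwaySet(
                pathway_id=fields[0], name=fields[1], members=frozenset(members)
            )
        )
    return sets


def read_config(path) -> dict:
    """YAML (or JSON) pipeline configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("configuration must be a mapping")
    return cfg


def write_table(df: pd.DataFrame, path, *, stage: str, params: dict | None = None,
                index: bool = True) -> Path:
    """Write a TSV with an audit-trail header comment (version, stage,
    parameters).  No timestamps: outputs of identical runs are
    byte-identical."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    parts = " ".join(f"{k}={v}" for k, v in (params or {}).items())
    header = f"# metadyn {__version__} | stage={stage}" + (
        f" | {parts}" if parts else ""
    )
    with open(path, "w") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, sep="\t", index=index)
    return path


# --------------------------------------------------------------------------
# pipeline driver


def run_pipeline(cfg: dict) -> dict:
    """Execute annotate -> fit -> fold-changes -> fingerprint -> enrich.

    ``cfg`` holds ``paths`` (matrix, meta, metabolites, gmt, out_dir),
    optional ``thresholds`` overriding :data:`DEFAULT_THRESHOLDS`,
    ``correction`` (bh | storey) and ``seed`` (recorded; the pipeline is
    deterministic).  Writes all stage TSVs plus ``run_log.json`` under
    out_dir and returns the in-memory result bundle.  On stage failure the
    files written so far are renamed with a ``.partial`` suffix and a
    stage-tagged :class:`PipelineError` is raised.
    """
    paths = cfg.get("paths", {})
    thresholds = {**DEFAULT_THRESHOLDS, **cfg.get("thresholds", {})}
    correction = cfg.get("correction", "bh")
    out_dir = Path(paths.get("out_dir", "."))
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    results: dict = {"thresholds": thresholds}

    def fail(stage: str, err: Exception):
        for f in written:
            f.rename(f.with_suffix(f.suffix + ".partial"))
        raise PipelineError(stage, str(err)) from err

    stage = "annotate"
    try:
        matrix = read_intensity_matrix(paths["matrix"])
        meta = read_sample_meta(paths["meta"])
        metabolites = read_metabolite_table(paths["metabolites"])
        library = chem.build_ion_library(metabolites)
        ion_mzs = [float(i) for i in matrix.index]
        annotations = chem.annotate_ions(
            ion_mzs, library, tolerance=thresholds["tolerance"]
        )
        ann_df = pd.DataFrame(
            [
                {
                    "ion_mz": a.ion_mz,
                    "metabolite_id": a.best_metabolite_id,
                    "expected_mz": a.ion_mz - a.mass_error,
                    "mass_error_da": a.mass_error,
                    "n_matches": len(a.all_matches),
                    "all_matches": ";".join(m[0] for m in a.all_matches),
                }
                for a in annotations
            ]
        )
        written.append(
            write_table(
                ann_df, out_dir / "annotations.tsv", stage=stage,
                params={"tolerance": thresholds["tolerance"]}, index=False,
            )
        )
        results["annotations"] = annotations
        annotated = {a.ion_mz for a in annotations}
        matrix = matrix.loc[[i for i in matrix.index if float(i) in annotated]]
        ion_met = {a.ion_mz: a.best_metabolite_id for a in annotations}
    except PipelineError:
        raise
    except Exception as err:  # noqa: BLE001 - stage-tagged re-raise
        fail(stage, err)

    stage = "fit-steady-state"
    try:
        model = steady_state.SteadyStateModel(
            matrix, meta, max_confluence=thresholds["max_confluence"]
        )
        fit = model.fit(p_threshold=thresholds["p_reliable"])
        written.append(
            write_table(
                fit.to_frame(), out_dir / "steady_state_fit.tsv", stage=stage,
                params={
                    "max_confluence": thresholds["max_confluence"],
                    "p_reliable": thresholds["p_reliable"],
                },
                index=False,
            )
        )
        results["fit"] = fit
    except Exception as err:  # noqa: BLE001
        fail(stage, err)

    stage = "fold-changes"
    try:
        fc = dynamics.compute_fold_changes(matrix, meta, fit)
        written.append(
            write_table(fc, out_dir / "fold_changes.tsv", stage=stage, index=False)
        )
        results["fold_changes"] = fc
        treatments = sorted(fc["treatment"].unique())
    except Exception as err:  # noqa: BLE001
        fail(stage, err)

    stage = "fingerprint"
    try:
        results["fingerprints"] = {}
        for trt in treatments:
            table = fingerprint.summarize_across_lines(fc, trt)
            conserved = fingerprint.select_conserved(
                table, fc_cut=thresholds["fc_cut"], p_cut=thresholds["p_cut"]
            )
            variable = fingerprint.select_variable(
                table, sd_cut=thresholds["sd_cut"]
            )
            table = table.assign(
                selected_conserved=table.index.isin(conserved),
                selected_variable=table.index.isin(variable),
            )
            written.append(
                write_table(
                    table, out_dir / f"fingerprint_{trt}.tsv", stage=stage,
                    params={
                        "treatment": trt,
                        "fc_cut": thresholds["fc_cut"],
                        "p_cut": thresholds["p_cut"],
                        "sd_cut": thresholds["sd_cut"],
                    },
                )
            )
            results["fingerprints"][trt] = table
    except Exception as err:  # noqa: BLE001
        fail(stage, err)

    stage = "enrich"
    try:
        results["enrichment"] = {}
        if paths.get("gmt"):
            pathways = read_pathway_gmt(paths["gmt"])
            universe_ions = [
                i for i in fit.reliable_ions if float(i) in ion_met
            ]
            universe = {ion_met[float(i)] for i in universe_ions}
            for trt, table in results["fingerprints"].items():
                for branch in ("conserved", "variable"):
                    sel_ions = table.index[table[f"selected_{branch}"]]
                    selected = {
                        ion_met[float(i)] for i in sel_ions
                        if float(i) in ion_met
                    } & universe
                    enr = fingerprint.enrich_pathways(
                        selected, universe, pathways,
                        q_cut=thresholds["q_cut"], method=correction,
                    )
                    written.append(
                        write_table(
                            enr, out_dir / f"enrichment_{trt}_{branch}.tsv",
                            stage=stage,
                            params={
                                "treatment": trt, "branch": branch,
                                "q_cut": thresholds["q_cut"],
                                "correction": correction,
                            },
                            index=False,
                        )
                    )
                    results["enrichment"][(trt, branch)] = enr
    except Exception as err:  # noqa: BLE001
        fail(stage, err)

    log = {
        "version": __version__,
        "seed": cfg.get("seed"),
        "thresholds": thresholds,
        "correction": correction,
        "n_ions_annotated": len(results["annotations"]),
        "n_ions_reliable": int(len(results["fit"].reliable_ions)),
        "median_cv_percent": (
            round(results["fit"].median_cv(), 4)
            if len(results["fit"].reliable_ions)
            else None
        ),
        "treatments": treatments,
        "outputs": [str(p) for p in written],
    }
    log_path = out_dir / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    print(json.dumps(log, sort_keys=True), file=sys.stderr)
    results["log"] = log
    return results


def write_fixture_bundle(out_dir, seed: int = 0) -> dict:
    """Generate and write the synthetic pipeline fixture bundle.

    Emits matrix.tsv, meta.tsv, metabolites.tsv, pathways.gmt,
    confluence.tsv and config.yaml under ``out_dir`` in the same dialects
    the pipeline reads.  Returns the paths.
    """
    from . import synthetic

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle = synthetic.generate_pipeline_bundle(seed)
    paths = {}
    params = {"seed": seed}
    paths["matrix"] = write_table(
        bundle["matrix"].rename_axis("ion_mz"), out_dir / "matrix.tsv",
        stage="make-fixtures", params=params,
    )
    paths["meta"] = write_table(
        bundle["meta"].rename_axis("sample_id"), out_dir / "meta.tsv",
        stage="make-fixtures", params=params,
    )
    paths["metabolites"] = write_table(
        bundle["metabolites"], out_dir / "metabolites.tsv",
        stage="make-fixtures", params=params, index=False,
    )
    gmt_path = out_dir / "pathways.gmt"
    with open(gmt_path, "w") as fh:
        for pid, (name, members) in bundle["pathways"].items():
            fh.write("\t".join([pid, name, *members]) + "\n")
    paths["gmt"] = gmt_path
    paths["confluence"] = write_table(
        bundle["confluence"], out_dir / "confluence.tsv",
        stage="make-fixtures", params=params, index=False,
    )
    config = {
        "paths": {
            "matrix": str(paths["matrix"]),
            "meta": str(paths["meta"]),
            "metabolites": str(paths["metabolites"]),
            "gmt": str(paths["gmt"]),
            "out_dir": str(out_dir / "results"),
        },
        "thresholds": dict(DEFAULT_THRESHOLDS),
        "correction": "bh",
        "seed": seed,
    }
    cfg_path = out_dir / "config.yaml"
    cfg_path.write_text(yaml.safe_dump(config, sort_keys=True))
    paths["config"] = cfg_path
    return paths
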