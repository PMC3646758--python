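"""Readers and writers for the pipeline's tabular formats.

All tabular data move through pandas: OD time series and chromatograms as
CSV, retention-time libraries, growth-parameter tables, quantification
tables, trajectory reports and phenotype matrices as TSV. Chromatogram
metadata travel in a YAML/JSON sidecar next to the trace CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .fame import Chromatogram, FAQuant, LibraryEntry, RTLibrary
from .growth import GrowthParameters, ODTimeSeries, TimepointSelection
from .lipids import LipidTrajectory
from .phenotype import PhenotypeMatrix, Score, SubstrateClass

__all__ = [
    "read_od_series", "write_od_series",
    "read_chromatogram", "write_chromatogram",
    "read_rt_library", "write_rt_library",
    "write_growth_parameters", "write_timepoints",
    "write_faquant", "write_trajectories",
    "read_phenotype_matrix", "write_phenotype_matrix",
]


def _err(path, exc):
    raise ValueError(f"malformed table {path}: {exc}") from exc


def read_od_series(path: str | Path, strain_label: str = "", medium_label: str = "") -> list[ODTimeSeries]:
    """Read OD600 records from CSV (time_h, od600[, replicate]) — one series
    per replicate."""
    try:
        df = pd.read_csv(path)
        df.columns = [c.strip() for c in df.columns]
        if "replicate" not in df.columns:
            df["replicate"] = "1"
        out = []
        for rep, grp in df.groupby("replicate", sort=False):
            grp = grp.sort_values("time_h")
            out.append(
                ODTimeSeries(
                    strain_label=strain_label or str(grp.get("strain", pd.Series(["?"])).iloc[0]),
                    medium_label=medium_label or str(grp.get("medium", pd.Series(["?"])).iloc[0]),
                    times=grp["time_h"].to_numpy(float),
                    od=grp["od600"].to_numpy(float),
                    replicate=str(rep),
                )
            )
        return out
    except (KeyError, ValueError, TypeError) as exc:
        _err(path, exc)


def write_od_series(series: ODTimeSeries, path: str | Path) -> None:
    pd.DataFrame(
        {"time_h": series.times, "od600": series.od, "replicate": series.replicate}
    ).to_csv(path, index=False)


def write_chromatogram(chrom: Chromatogram, path: str | Path, sidecar: str | Path | None = None) -> None:
    """Write trace CSV (rt_min, intensity_pA) plus a metadata sidecar
    (defaults to <path>.meta.yaml)."""
    path = Path(path)
    pd.DataFrame({"rt_min": chrom.rt, "intensity_pA": chrom.intensity}).to_csv(path, index=False)
    meta = {
        "sample_id": chrom.sample_id,
        "aliquot_od_units": chrom.aliquot_od_units,
        "aliquot_cdw_mg": chrom.aliquot_cdw_mg,
        "is_mass_ug": chrom.is_mass_ug,
        "notes": list(chrom.notes),
    }
    sidecar = Path(sidecar) if sidecar else path.with_suffix(path.suffix + ".meta.yaml")
    sidecar.write_text(yaml.safe_dump(meta, sort_keys=False))


def read_chromatogram(path: str | Path, sidecar: str | Path | None = None) -> Chromatogram:
    path = Path(path)
    try:
        df = pd.read_csv(path)
        rt = df["rt_min"].to_numpy(float)
        y = df["intensity_pA"].to_numpy(float)
    except (KeyError, ValueError, TypeError) as exc:
        _err(path, exc)
    meta: dict = {}
    sidecar = Path(sidecar) if sidecar else path.with_suffix(path.suffix + ".meta.yaml")
    if sidecar.exists():
        if sidecar.suffix == ".json":
            meta = json.loads(sidecar.read_text())
        else:
            meta = yaml.safe_load(sidecar.read_text()) or {}
    return Chromatogram(
        rt=rt,
        intensity=y,
        sample_id=meta.get("sample_id", path.stem),
        aliquot_od_units=meta.get("aliquot_od_units", 10.0),
        aliquot_cdw_mg=meta.get("aliquot_cdw_mg"),
        is_mass_ug=meta.get("is_mass_ug", 75.0),
        notes=tuple(meta.get("notes", ())),
    )


def read_rt_library(path: str | Path) -> RTLibrary:
    """Read a library CSV (fa_name, rt_min, response_factor, is_internal_standard)."""
    try:
        df = pd.read_csv(path)
        entries = tuple(
            LibraryEntry(
                fa_name=str(r.fa_name),
                rt=float(r.rt_min),
                response_factor=float(getattr(r, "response_factor", 1.0)),
                is_internal_standard=bool(getattr(r, "is_internal_standard", False)),
            )
            for r in df.itertuples(index=False)
        )
        return RTLibrary(entries)
    except (AttributeError, KeyError, ValueError, TypeError) as exc:
        _err(path, exc)


def write_rt_library(lib: RTLibrary, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "fa_name": e.fa_name,
                "rt_min": e.rt,
                "response_factor": e.response_factor,
                "is_internal_standard": e.is_internal_standard,
            }
            for e in lib.entries
        ]
    ).to_csv(path, index=False)


def growth_parameters_frame(params: list[GrowthParameters]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "strain": p.strain_label,
                "medium": p.medium_label,
                "mu_max": p.mu_max,
                "generation_time": p.generation_time,
                "lag": p.lag,
                "od_max": p.od_max,
                "r2": p.r2,
                "no_growth": p.no_growth,
            }
            for p in params
        ]
    )


def write_growth_parameters(params: list[GrowthParameters], path: str | Path) -> None:
    growth_parameters_frame(params).to_csv(path, sep="\t", index=False, float_format="%.4f")


def write_timepoints(rows: list[tuple[str, str, TimepointSelection]], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "strain": strain,
                "medium": medium,
                "t_fifth": sel.t_fifth,
                "t_half": sel.t_half,
                "t_max": sel.t_max,
                "od_fifth": sel.od_fifth,
                "od_half": sel.od_half,
                "od_max": sel.od_max_reached,
            }
            for strain, medium, sel in rows
        ]
    ).to_csv(path, sep="\t", index=False, float_format="%.3f")


def write_faquant(q: FAQuant, path: str | Path) -> None:
    """Per-FA table plus a one-row total summary appended as a comment."""
    df = pd.DataFrame(
        [
            {
                "fa_name": name,
                "mass_ug": q.masses_ug[name],
                "mg_per_g_cdw": q.mg_per_g_cdw[name],
                "fraction": q.fractions.get(name, float("nan")),
            }
            for name in sorted(q.masses_ug)
        ]
    )
    with open(path, "w") as fh:
        df.to_csv(fh, sep="\t", index=False, float_format="%.4f")
        fh.write(f"# sample\t{q.sample_id}\tpct_cdw_total\t{q.pct_cdw_total:.4f}\n")


def write_trajectories(trajectories: list[LipidTrajectory], report_path: str | Path,
                       composition_path: str | Path | None = None) -> None:
    """Write the per-strain trajectory report and, optionally, a long-format
    composition table (strain, medium, timepoint, fa_name, mg_per_g_cdw)."""
    rows, comp_rows = [], []
    for tr in trajectories:
        pct = {p.label: p.pct_cdw for p in tr.points}
        rows.append(
            {
                "strain": tr.strain_label,
                "medium": tr.medium_label,
                "pct_cdw_fifth": pct.get("fifth"),
                "pct_cdw_half": pct.get("half"),
                "pct_cdw_max": pct.get("max"),
                "pattern": tr.pattern,
                "max_pct_cdw": tr.max_pct_cdw,
                "oleaginous": tr.oleaginous,
                "major_compound": "|".join(sorted(tr.major_compound_at_max))
                if tr.major_compound_at_max
                else None,
            }
        )
        for p in tr.points:
            for fa, v in p.composition_mg_g.items():
                comp_rows.append(
                    {
                        "strain": tr.strain_label,
                        "medium": tr.medium_label,
                        "timepoint": p.label,
                        "fa_name": fa,
                        "mg_per_g_cdw": v,
                    }
                )
    pd.DataFrame(rows).to_csv(report_path, sep="\t", index=False, float_format="%.3f")
    if composition_path is not None:
        pd.DataFrame(comp_rows).to_csv(composition_path, sep="\t", index=False, float_format="%.3f")


def write_phenotype_matrix(matrix: PhenotypeMatrix, path: str | Path) -> None:
    rows = [
        {
            "strain": strain,
            "substrate": sub,
            "substrate_class": matrix.substrate_classes.get(sub, SubstrateClass.SUGAR_OTHER).value,
            "medium": medium,
            "score": score.value,
            "halo": matrix.halo.get((strain, sub, medium), ""),
        }
        for (strain, sub, medium), score in matrix.scores.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_phenotype_matrix(path: str | Path) -> PhenotypeMatrix:
    """Read a long-format TSV (strain, substrate, substrate_class, medium,
    score[, halo])."""
    try:
        df = pd.read_csv(path, sep="\t")
        strains = list(dict.fromkeys(df["strain"]))
        substrates = list(dict.fromkeys(df["substrate"]))
        m = PhenotypeMatrix(
            strains=strains,
            substrates=substrates,
            substrate_classes={
                str(r.substrate): SubstrateClass(str(r.substrate_class))
                for r in df.itertuples(index=False)
            }
            if "substrate_class" in df.columns
            else {},
        )
        for r in df.itertuples(index=False):
            key = (str(r.strain), str(r.substrate), str(r.medium))
            m.scores[key] = Score(str(r.score))
            halo = getattr(r, "halo", "")
            if isinstance(halo, bool) or halo in ("True", "False"):
                m.halo[key] = halo if isinstance(halo, bool) else halo == "True"
        return m
    except (KeyError, ValueError, TypeError) as exc:
        _err(path, exc)
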