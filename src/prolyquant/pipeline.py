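"""End-to-end orchestration: simulate -> analyze -> report.

A :class:`RunConfig` names a mode (exsy, ms, foci, survival), the input
files, an output directory and module parameters; :func:`run_pipeline`
dispatches to the matching module chain and writes deterministic TSV tables
plus a JSON run log carrying the exact parameters and seed.  Configs
round-trip to flat TOML files (one ``key = value`` per line).
"""

from __future__ import annotations

import json
import logging
import tomllib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import exchange, imaging, nativems

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "load_config", "save_config", "run_pipeline",
           "write_report", "load_species_config", "plot_exsy_fit",
           "plot_spectrum"]

MODES = ("exsy", "ms", "foci", "survival")


@dataclass
class RunConfig:
    mode: str
    inputs: list[str] = field(default_factory=list)
    out_dir: str = "results"
    seed: int | None = None
    species_config: str | None = None  # ms mode
    params: dict = field(default_factory=dict)
    log_level: str = "INFO"
    make_plots: bool = False

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {MODES}")

    def validate_paths(self) -> None:
        for p in list(self.inputs) + ([self.species_config] if self.species_config else []):
            if not Path(p).exists():
                raise FileNotFoundError(f"input file not found: {p}")


def save_config(config: RunConfig, path) -> None:
    """Write a config as flat TOML (lossless round trip via load_config)."""
    lines = []
    for key, value in asdict(config).items():
        if value is None:
            continue
        if isinstance(value, str):
            lines.append(f'{key} = "{value}"')
        elif isinstance(value, bool):
            lines.append(f"{key} = {str(value).lower()}")
        elif isinstance(value, (int, float)):
            lines.append(f"{key} = {value}")
        elif isinstance(value, list):
            items = ", ".join(f'"{v}"' if isinstance(v, str) else str(v) for v in value)
            lines.append(f"{key} = [{items}]")
        elif isinstance(value, dict):
            def _fmt(v):
                if isinstance(v, str):
                    return f'"{v}"'
                if isinstance(v, bool):
                    return str(v).lower()
                return str(v)

            items = ", ".join(f"{k} = {_fmt(v)}" for k, v in value.items())
            lines.append(f"{key} = {{{items}}}")
        else:  # pragma: no cover
            raise TypeError(f"cannot serialize config field {key} of type {type(value)}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_config(path) -> RunConfig:
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    return RunConfig(**data)


def load_species_config(path) -> list[nativems.Species]:
    """Read a species table and expand ligands into 1:1 complexes.

    Columns: ``name``, ``kind`` (protein|ligand), and either ``mass`` (Da) or
    ``sequence`` (+ optional integer ``phospho``).  Exactly one protein row is
    required; every ligand row yields a protein:ligand complex species.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    need = {"name", "kind"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: species config needs columns {sorted(need)}")

    def row_mass(row) -> float:
        if "mass" in row and pd.notna(row.get("mass")):
            return float(row["mass"])
        if "sequence" in row and pd.notna(row.get("sequence")):
            phospho = int(row["phospho"]) if pd.notna(row.get("phospho", np.nan)) else 0
            return nativems.peptide_mass(str(row["sequence"]), phospho)
        raise ValueError(f"{path}: row {row['name']!r} has neither mass nor sequence")

    proteins = df[df["kind"] == "protein"]
    if len(proteins) != 1:
        raise ValueError(f"{path}: exactly one protein row required, got {len(proteins)}")
    prow = proteins.iloc[0]
    protein = nativems.Species(str(prow["name"]), row_mass(prow), "protein")
    species = [protein]
    for _, row in df[df["kind"] == "ligand"].iterrows():
        species.append(nativems.make_complex(protein, str(row["name"]), row_mass(row)))
    return species


# ------------------------------------------------------------------ stages --

def _run_exsy(config: RunConfig, out: Path) -> dict[str, pd.DataFrame]:
    rows = []
    curves = []
    p = config.params
    for path in config.inputs:
        series = exchange.read_mixing_series(path)
        table = exchange.build_ratio_series(series)
        fit = exchange.fit_exchange(
            table,
            weighted=p.get("weighted"),
            se_method=p.get("se_method", "covariance"),
            seed=config.seed,
        )
        rows.append(
            {
                "sample": series.label,
                "k_ct": fit.k_ct,
                "k_tc": fit.k_tc,
                "k_ex": fit.k_ex,
                "se_k_ct": fit.se_k_ct,
                "se_k_tc": fit.se_k_tc,
                "se_k_ex": fit.se_k_ex,
                "residual_ss": fit.residual_ss,
                "n_points": fit.n_points,
                "converged": fit.converged,
            }
        )
        curves.append((series.label, table, fit))
    report = pd.DataFrame(rows)
    if config.make_plots:
        for label, table, fit in curves:
            stem = Path(label).stem or "series"
            plot_exsy_fit(table, fit, out / f"exsy_fit_{stem}.png")
    return {"exsy_fit": report}


def _run_ms(config: RunConfig, out: Path) -> dict[str, pd.DataFrame]:
    if not config.species_config:
        raise ValueError("ms mode requires species_config")
    species = load_species_config(config.species_config)
    p = config.params
    charge_range = (int(p.get("charge_min", 5)), int(p.get("charge_max", 15)))
    tol_mz = float(p.get("tol_mz", 1.5))
    min_snr = float(p.get("min_snr", 5.0))
    species_rows, bound_rows = [], []
    for path in config.inputs:
        spectrum = nativems.read_spectrum(path)
        peaks = nativems.pick_peaks(spectrum, min_snr=min_snr)
        assignments, unmatched = nativems.assign_charge_states(
            peaks, species, charge_range=charge_range, tol_mz=tol_mz
        )
        abundances = {
            a.species: nativems.charge_normalized_abundance(a) for a in assignments
        }
        summary = nativems.percent_bound(abundances)
        for a in assignments:
            species_rows.append(
                {
                    "spectrum": str(path),
                    "species": a.species.name,
                    "neutral_mass": a.species.neutral_mass,
                    "charges_matched": ",".join(
                        str(z) for z in sorted(a.per_charge_intensity)
                    ),
                    "abundance": summary.abundances[a.species.name],
                }
            )
        for name, pct in sorted(summary.percent_bound.items()):
            bound_rows.append(
                {"spectrum": str(path), "complex": name, "percent_bound": pct}
            )
        if unmatched:
            logger.info("%s: %d unmatched peaks", path, len(unmatched))
        if config.make_plots:
            plot_spectrum(spectrum, assignments, out / f"spectrum_{Path(path).stem}.png")
    return {
        "ms_species": pd.DataFrame(species_rows),
        "ms_percent_bound": pd.DataFrame(bound_rows),
    }


def _run_foci(config: RunConfig, out: Path) -> dict[str, pd.DataFrame]:
    p = config.params
    min_area = int(p.get("min_area", 100))
    channel_names = list(p.get("channels", ["dna", "marker"]))
    frames = []
    for path in config.inputs:
        img = imaging.read_image(path)
        names = channel_names[: img.shape[0]]
        labels = imaging.segment_nuclei(img[0], min_area=min_area)
        channels = {name: img[i] for i, name in enumerate(names)}
        df = imaging.measure_image(channels, labels)
        df.insert(0, "image", str(path))
        frames.append(df)
    per_nucleus = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    summary = (
        per_nucleus.groupby("channel")["ctcf"].agg(["count", "mean", "std"]).reset_index()
        if len(per_nucleus)
        else pd.DataFrame()
    )
    return {"foci_per_nucleus": per_nucleus, "foci_summary": summary}


def _run_survival(config: RunConfig, out: Path) -> dict[str, pd.DataFrame]:
    frames = []
    for path in config.inputs:
        counts = pd.read_csv(path, sep=None, engine="python")
        df = imaging.survival_table(counts)
        df.insert(0, "table", str(path))
        frames.append(df)
    return {"survival": pd.concat(frames, ignore_index=True)}


_DISPATCH = {"exsy": _run_exsy, "ms": _run_ms, "foci": _run_foci,
             "survival": _run_survival}


def run_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Dispatch a configured run and write its report tables and log."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results = _DISPATCH[config.mode](config, out)
    write_report(results, out)
    log = {
        "prolyquant_version": __version__,
        "mode": config.mode,
        "seed": config.seed,
        "inputs": list(config.inputs),
        "params": config.params,
        "species_config": config.species_config,
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    return results


def write_report(results: dict[str, pd.DataFrame], out_dir) -> list[Path]:
    """Write each result table as TSV with deterministic column order."""
    if not results:
        raise ValueError("no results to report")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name in sorted(results):
        path = out / f"{name}.tsv"
        results[name].to_csv(path, sep="\t", index=False, float_format="%.10g")
        written.append(path)
    return written


# ------------------------------------------------------------------ plots ---

def plot_exsy_fit(ratio_table: pd.DataFrame, fit, path) -> None:
    """Data with error bars plus the fitted two-site build-up curve."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = np.asarray(ratio_table["t_mix"], dtype=float)
    fig, ax = plt.subplots(figsize=(5, 4))
    yerr = ratio_table.get("ratio_error")
    ax.errorbar(t, ratio_table["ratio"], yerr=yerr, fmt="o", capsize=3, label="data")
    tt = np.linspace(0, t.max() * 1.05, 200)
    ax.plot(tt, exchange.exsy_ratio_model(tt, fit.k_ct, fit.k_tc), "-",
            label=f"fit: $k_{{ex}}$ = {fit.k_ex:.2f} ± {fit.se_k_ex:.2f} s$^{{-1}}$")
    ax.set_xlabel("mixing time (s)")
    ax.set_ylabel("$I_{ct}/I_{tt}$")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_spectrum(spectrum, assignments, path) -> None:
    """Spectrum with assigned charge-state peaks annotated per species."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(spectrum.mz, spectrum.intensity, "k-", lw=0.7)
    for a in assignments:
        if not a.matched_mz:
            continue
        heights = [
            spectrum.intensity[np.argmin(np.abs(spectrum.mz - m))] for m in a.matched_mz
        ]
        ax.plot(a.matched_mz, heights, "v", label=a.species.name)
    ax.set_xlabel("m/z")
    ax.set_ylabel("intensity")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
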