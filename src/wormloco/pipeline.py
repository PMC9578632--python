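"""End-to-end orchestration: images or tables -> scores -> statistics -> report.

Also houses the ethanol dosing calculator (how many microlitres of pure
ethanol to infuse into an agar plate for a target molar concentration)
and the run configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .quant import CorralROI, ImageStack, score_trial
from .stats import StatsReport, analyze_experiment, validate_trial_records
from .synthetic import (RenderConfig, SimDesign, WormKinematics,
                        generate_trial_table, render_stack,
                        simulate_worm_paths)

logger = logging.getLogger("wormloco")

__all__ = [
    "ETHANOL_DENSITY_G_PER_ML",
    "ETHANOL_MOLAR_MASS",
    "PURE_ETHANOL_MOLARITY",
    "DosePlan",
    "RunConfig",
    "ethanol_dose",
    "load_trial_table",
    "roi_from_spec",
    "score_image_trials",
    "simulate_image_trials",
    "run_experiment",
]

# molarity of pure ethanol from density 0.789 g/mL and molar mass 46.07 g/mol
ETHANOL_DENSITY_G_PER_ML = 0.789
ETHANOL_MOLAR_MASS = 46.07
PURE_ETHANOL_MOLARITY = ETHANOL_DENSITY_G_PER_ML / ETHANOL_MOLAR_MASS * 1000.0  # ~17.13 M


def ethanol_dose(agar_volume_ml: float, target_mm: float,
                 purity: float = 1.0) -> float:
    """Microlitres of ethanol to infuse for a target agar concentration.

    volume_uL = target_mM * agar_mL / (purity * C_pure), with C_pure the
    molarity of pure ethanol (~17.13 M).  The small volume added by the
    dose itself is neglected, matching standard plate-infusion
    arithmetic (280 uL into a 12 mL plate for 400 mM).
    """
    if agar_volume_ml <= 0:
        raise ValueError("agar volume must be > 0")
    if target_mm < 0:
        raise ValueError("target concentration must be >= 0")
    if not 0 < purity <= 1:
        raise ValueError("purity must be in (0, 1]")
    return target_mm * agar_volume_ml / (purity * PURE_ETHANOL_MOLARITY)


@dataclass
class DosePlan:
    """A dosing plan for one treatment plate."""

    agar_volume_ml: float = 12.0
    target_concentration_mm: float = 400.0
    ethanol_purity: float = 1.0

    @property
    def ethanol_volume_ul(self) -> float:
        return ethanol_dose(self.agar_volume_ml, self.target_concentration_mm,
                            self.ethanol_purity)


@dataclass
class RunConfig:
    """Configuration of one analysis run.

    mode:
      * ``simulate`` — draw a yoked trial table from a SimDesign and analyse it;
      * ``table`` — ingest an existing trial CSV (or XLSX with a column map);
      * ``images`` — score TIFF stacks listed in a metadata CSV, then analyse.
    """

    mode: str = "simulate"
    out_dir: Path = Path("wormloco_run")
    seed: int = 0
    alpha: float = 0.05
    ss_type: int = 3
    blind: bool = False
    # table mode
    table_path: Optional[Path] = None
    column_map: Optional[dict] = None
    sheet_name: int | str = 0
    # images mode
    metadata_path: Optional[Path] = None
    stacks_dir: Optional[Path] = None
    roi_spec: Optional[dict] = None
    # simulate mode
    paradigm: str = "chronic"
    design_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "table", "images"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.mode == "table" and self.table_path is None:
            raise ValueError("table mode requires table_path")
        if self.mode == "images" and self.metadata_path is None:
            raise ValueError("images mode requires metadata_path")
        self.out_dir = Path(self.out_dir)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(**payload)


def load_trial_table(path, column_map: Optional[dict] = None,
                     sheet_name: int | str = 0) -> pd.DataFrame:
    """Read a trial table from CSV or XLSX.

    ``column_map`` maps source column names to the canonical schema
    (pair_id, plate_id, generation, lineage, condition, n_worms,
    area_per_worm), so supporting-data workbooks with their own headers
    can be ingested without editing the file.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        table = pd.read_excel(path, sheet_name=sheet_name)
    else:
        table = pd.read_csv(path)
    if column_map:
        table = table.rename(columns=column_map)
    missing = {"pair_id", "generation", "lineage", "condition", "n_worms",
               "area_per_worm"} - set(table.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    if "plate_id" not in table.columns:
        table["plate_id"] = table.get("pair_id", "")
    table["generation"] = table["generation"].astype(str).str.upper()
    table["lineage"] = table["lineage"].astype(str).str.lower()
    table["condition"] = table["condition"].astype(str).str.lower()
    return validate_trial_records(table)


def roi_from_spec(spec: Optional[dict], frame_shape) -> CorralROI:
    """Build a CorralROI from its JSON-style specification."""
    if spec is None or spec.get("shape", "full") == "full":
        return CorralROI.full(frame_shape)
    kind = spec["shape"]
    if kind == "rectangle":
        return CorralROI.rectangle(frame_shape, spec["y0"], spec["y1"],
                                   spec["x0"], spec["x1"])
    if kind == "circle":
        return CorralROI.circle(frame_shape, tuple(spec["center"]), spec["radius"])
    raise ValueError(f"unknown ROI shape {kind!r}")


def score_image_trials(metadata: pd.DataFrame, stacks_dir: Path,
                       roi_spec: Optional[dict] = None) -> pd.DataFrame:
    """Score every stack listed in an images-mode metadata table.

    The metadata CSV must contain pair_id, plate_id, generation,
    lineage, condition, n_worms and stack_path (relative to
    ``stacks_dir``).  Returns canonical trial records with a
    ``threshold`` column of the IsoData thresholds used.
    """
    required = {"pair_id", "generation", "lineage", "condition", "n_worms",
                "stack_path"}
    missing = required - set(metadata.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    rows = []
    for _, row in metadata.iterrows():
        stack = ImageStack.from_tiff(Path(stacks_dir) / row["stack_path"])
        roi = roi_from_spec(roi_spec, stack.frame_shape)
        score = score_trial(stack, roi, int(row["n_worms"]))
        rows.append({
            "pair_id": row["pair_id"],
            "plate_id": row.get("plate_id", row["pair_id"]),
            "generation": str(row["generation"]).upper(),
            "lineage": str(row["lineage"]).lower(),
            "condition": str(row["condition"]).lower(),
            "n_worms": int(row["n_worms"]),
            "area_per_worm": score.area_per_worm,
            "threshold": score.threshold_used,
            "no_foreground": score.no_foreground,
        })
    records = pd.DataFrame(rows)
    validate_trial_records(records)
    return records


def simulate_image_trials(out_dir: Path, n_pairs: int = 2,
                          generation: str = "F3",
                          intoxication_on_etoh: float = 0.8,
                          lineage_intoxication_shift: float = 0.0,
                          kin: Optional[WormKinematics] = None,
                          cfg: Optional[RenderConfig] = None,
                          n_worms: int = 10, seed: int = 0,
                          shared_pair_seed: bool = False) -> pd.DataFrame:
    """Render a small imaged experiment: TIFF stacks plus a metadata CSV.

    For each yoked pair, both lineages are recorded at baseline
    (intoxication 0) and on ethanol (the given intoxication factor,
    optionally shifted for the EtOH lineage).  With
    ``shared_pair_seed=True`` the two lineages of a pair reuse the same
    simulation seed, producing identical stacks and hence exactly-zero
    yoked differences — useful as a known-truth fixture.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    kin = kin or WormKinematics()
    cfg = cfg or RenderConfig()
    ss = np.random.SeedSequence(seed)
    rows = []
    for k in range(n_pairs):
        pair_seeds = ss.spawn(1)[0].generate_state(2) % (2**31)
        for li, lineage in enumerate(("control", "etoh")):
            wseed = int(pair_seeds[0] if shared_pair_seed else pair_seeds[li])
            for condition in ("baseline", "etoh"):
                intox = 0.0 if condition == "baseline" else float(
                    np.clip(intoxication_on_etoh
                            + (lineage_intoxication_shift if lineage == "etoh" else 0.0),
                            0.0, 1.0))
                kin_trial = WormKinematics(**{**asdict(kin), "intoxication": intox})
                # worm placement/gait reuses wseed; rendering noise varies per condition
                paths = simulate_worm_paths(kin_trial, cfg, n_worms, seed=wseed)
                cfg_trial = RenderConfig(**{**asdict(cfg),
                                            "seed": wseed * 2 + (condition == "etoh")})
                stack = render_stack(paths, cfg_trial)
                name = f"pair{k:02d}_{lineage}_{condition}.tif"
                stack.to_tiff(out_dir / name)
                rows.append({"pair_id": f"pair{k:02d}", "plate_id": f"plate{k:02d}",
                             "generation": generation, "lineage": lineage,
                             "condition": condition, "n_worms": n_worms,
                             "stack_path": name})
    metadata = pd.DataFrame(rows)
    metadata.to_csv(out_dir / "metadata.csv", index=False)
    return metadata


def _blind_code(records: pd.DataFrame, seed: int) -> tuple[pd.DataFrame, dict]:
    """Shuffle-code lineage labels for intermediate outputs."""
    rng = np.random.default_rng(seed)
    codes = ["group_A", "group_B"]
    rng.shuffle(codes)
    mapping = {"control": codes[0], "etoh": codes[1]}
    coded = records.copy()
    coded["lineage"] = coded["lineage"].map(mapping)
    return coded, mapping


def run_experiment(config: RunConfig) -> tuple[StatsReport, dict]:
    """Execute a full run and write its artifacts.

    Writes to ``config.out_dir``: trials.csv (scored or ingested
    records; blind-coded lineages if requested), yoked.csv (normalised
    values and ranked yoked differences), report.json, report.txt, and
    run_log.json recording seeds, thresholds and the package version.
    Returns the StatsReport and a dict of artifact paths.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"version": __version__, "mode": config.mode,
                 "seed": config.seed, "alpha": config.alpha,
                 "ss_type": config.ss_type}

    if config.mode == "simulate":
        design_kwargs = dict(config.design_overrides)
        design_kwargs.setdefault("seed", config.seed)
        design = (SimDesign.intermittent(**design_kwargs)
                  if config.paradigm == "intermittent"
                  else SimDesign.chronic(**design_kwargs))
        records = generate_trial_table(design)
        log["design"] = {k: (dict(v) if isinstance(v, dict) else
                             list(v) if isinstance(v, tuple) else v)
                         for k, v in asdict(design).items()}
        log["truncated_fraction"] = records.attrs.get("truncated_fraction", 0.0)
    elif config.mode == "table":
        records = load_trial_table(config.table_path, config.column_map,
                                   config.sheet_name)
        log["table_path"] = str(config.table_path)
    else:  # images
        metadata = pd.read_csv(config.metadata_path)
        stacks_dir = config.stacks_dir or Path(config.metadata_path).parent
        records = score_image_trials(metadata, stacks_dir, config.roi_spec)
        log["metadata_path"] = str(config.metadata_path)
        log["thresholds"] = {str(p): (None if t is None or pd.isna(t) else float(t))
                             for p, t in zip(metadata["stack_path"],
                                             records["threshold"])}

    report = analyze_experiment(records, alpha=config.alpha,
                                ss_type=config.ss_type)

    records_out = records
    if config.blind:
        records_out, mapping = _blind_code(records, config.seed)
        log["blind_mapping"] = mapping  # unblinding key lives only in the run log

    artifacts = {
        "trials": out / "trials.csv",
        "yoked": out / "yoked.csv",
        "report_json": out / "report.json",
        "report_txt": out / "report.txt",
        "run_log": out / "run_log.json",
    }
    records_out.to_csv(artifacts["trials"], index=False)
    yoked_ranked = report.yoked.sort_values("yoked_difference").reset_index(drop=True)
    yoked_ranked["rank"] = np.arange(1, len(yoked_ranked) + 1)
    yoked_ranked.to_csv(artifacts["yoked"], index=False)
    artifacts["report_json"].write_text(report.to_json())
    artifacts["report_txt"].write_text(report.format_table() + "\n")
    artifacts["run_log"].write_text(json.dumps(log, indent=2, sort_keys=True,
                                               default=str))
    logger.info("run complete: %d trials, report in %s", len(records), out)
    return report, {k: str(v) for k, v in artifacts.items()}
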