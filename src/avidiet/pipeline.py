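"""Pipeline orchestration: configuration, logging and staged execution.

``run_pipeline`` ties the stages together — read and filter episodes, tally
per species, raw proportions and seasonal tests, Bayesian imputation, and
(when a stomach table is supplied) count proportions and RMSD comparison —
writing tidy CSV artifacts plus a plain-text summary report.  All
randomness flows from one master seed, and log lines are stage-tagged and
timestamp-free so reruns with the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import episodes as ep
from . import rop as rop_mod
from . import stomach as st
from .model import DietImputationModel, MopModelSpec
from .schema import CategorySchema


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and input context."""


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    ``mop`` holds overrides for :class:`MopModelSpec` fields; the master
    ``seed`` replaces the spec seed so one integer controls everything.
    """

    episodes: str
    outdir: str
    stomach: str | None = None
    species: list[str] = field(default_factory=list)
    min_specimens: int = st.MIN_SPECIMENS
    seed: int = 0
    raw_reports: bool = False
    save_draws: bool = False
    mop: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise PipelineError(f"config: unknown key(s) {sorted(unknown)}")
        if "episodes" not in payload or "outdir" not in payload:
            raise PipelineError("config: 'episodes' and 'outdir' are required")
        return cls(**payload)

    def model_spec(self) -> MopModelSpec:
        return MopModelSpec(**{**self.mop, "seed": self.seed})


def _slug(species: str) -> str:
    return species.lower().replace(" ", "_")


class _Log:
    """Deterministic stage-tagged plain-text log."""

    def __init__(self, path: Path):
        self.path = path
        self.lines: list[str] = []

    def write(self, stage: str, message: str) -> None:
        self.lines.append(f"[{stage}] {message}")
        self.path.write_text("\n".join(self.lines) + "\n")


def load_and_filter(config: RunConfig, schema: CategorySchema, log: _Log):
    """Read the episode file, expand multi-records, apply exclusion filters."""
    reader = ep.read_raw_reports if config.raw_reports else ep.read_episodes
    try:
        raw = reader(config.episodes, schema)
    except Exception as exc:
        raise PipelineError(f"episodes stage: {exc}") from exc
    filtered = ep.apply_filters(raw)
    log.write("episodes", f"read {len(raw)} episodes from {config.episodes}")
    log.write("episodes", f"retained {len(filtered)} after filters "
              f"(dropped {len(raw) - len(filtered)})")
    return filtered


def run_pipeline(config: RunConfig, schema: CategorySchema | None = None) -> dict[str, Path]:
    """Execute the full pipeline and return the written artifact paths."""
    schema = schema or CategorySchema.default()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = _Log(outdir / "pipeline.log")
    artifacts: dict[str, Path] = {"log": log.path}

    episodes = load_and_filter(config, schema, log)
    species_list = config.species or ep.species_in(episodes)
    if not species_list:
        raise PipelineError("episodes stage: no species in input")

    # ------------------------------------------------------------- tally
    summary = ep.summary_table(episodes, schema)
    summary = summary[summary["species"].isin(species_list)]
    path = outdir / "summary.csv"
    summary.to_csv(path, index=False)
    artifacts["summary"] = path
    log.write("tally", f"tallied {len(species_list)} species")

    # ------------------------------------------------- rop + seasonal tests
    seasonal_rows = []
    mop_tables: dict[str, object] = {}
    rop_id_tables: dict[str, object] = {}
    diag_rows = []
    for species in species_list:
        counts = ep.tally(episodes, species, schema)
        if counts.total == 0:
            log.write("rop", f"{species}: no episodes, skipped")
            continue
        for kind, table in (
            ("rop", rop_mod.compute_rop(counts)),
            ("rop_identified", rop_mod.rop_identified_only(counts)),
            ("location", rop_mod.location_profile(counts)),
        ):
            p = outdir / f"{kind}_{_slug(species)}.csv"
            table.to_csv(p)
            artifacts[f"{kind}_{species}"] = p
        rop_id_tables[species] = rop_mod.rop_identified_only(counts)
        for res in (rop_mod.seasonal_animal_test(counts),
                    rop_mod.seasonal_ground_test(counts)):
            seasonal_rows.append(
                {"species": species, "trait": res.trait, "defined": res.defined,
                 "statistic": res.statistic, "p_one_sided": res.p_one_sided,
                 "direction_ok": res.direction_ok}
            )
        log.write("rop", f"{species}: {counts.total} episodes "
                  f"({counts.total - counts.n_identified} unidentified)")

        # --------------------------------------------------------- mop
        try:
            results = DietImputationModel(counts, spec=config.model_spec()).fit()
        except Exception as exc:
            raise PipelineError(f"mop stage ({species}): {exc}") from exc
        mop_table = results.mop()
        mop_tables[species] = mop_table
        p = outdir / f"mop_{_slug(species)}.csv"
        mop_table.to_csv(p)
        artifacts[f"mop_{species}"] = p
        if config.save_draws:
            p = outdir / f"mop_draws_{_slug(species)}.csv"
            _draws_long(results).to_csv(p, index=False)
            artifacts[f"mop_draws_{species}"] = p
        if results.spec.chains > 1:
            diag = results.diagnostics()
            diag.insert(0, "species", species)
            diag_rows.append(diag)
        log.write("mop", f"{species}: acceptance "
                  f"{results.acceptance_rate:.3f}")

    seasonal = pd.DataFrame(seasonal_rows)
    path = outdir / "seasonal_tests.csv"
    seasonal.to_csv(path, index=False)
    artifacts["seasonal_tests"] = path
    if diag_rows:
        path = outdir / "mop_diagnostics.csv"
        pd.concat(diag_rows).to_csv(path, index=False)
        artifacts["mop_diagnostics"] = path

    # --------------------------------------------------------- comparison
    rmsd_frames = []
    if config.stomach is None:
        log.write("compare", "no stomach table configured; comparison skipped")
    else:
        try:
            records = st.read_stomach(config.stomach, schema)
        except Exception as exc:
            raise PipelineError(f"stomach stage: {exc}") from exc
        records = st.filter_min_specimens(records, config.min_specimens)
        log.write("compare", f"{len(records)} stomach records after "
                  f"min-specimen filter (threshold {config.min_specimens})")
        cp_tables = {}
        for species in species_list:
            sp_records = [r for r in records if r.species == species]
            if not sp_records:
                continue
            cp = st.compute_cp(sp_records, schema, species=species)
            cp_tables[species] = cp
            p = outdir / f"cp_{_slug(species)}.csv"
            cp.to_csv(p)
            artifacts[f"cp_{species}"] = p
        if cp_tables:
            for label, tables in (("ROP", rop_id_tables), ("MOP", mop_tables)):
                frame = st.rmsd_summary(tables, cp_tables, schema.identified_items)
                frame.insert(0, "estimator", label)
                rmsd_frames.append(frame)
            for item in schema.identified_items:
                try:
                    res = st.rmsd_compare(mop_tables, cp_tables, item)
                except ValueError:
                    continue
                p = outdir / f"comparison_{_slug(item)}.csv"
                res.to_frame().to_csv(p, index=False)
                artifacts[f"comparison_{item}"] = p
        else:
            log.write("compare", "no overlapping species; comparison skipped")
    if rmsd_frames:
        rmsd = pd.concat(rmsd_frames, ignore_index=True)
        path = outdir / "rmsd_summary.csv"
        rmsd.to_csv(path, index=False)
        artifacts["rmsd_summary"] = path

    # ------------------------------------------------------------- report
    report_path = outdir / "report.txt"
    with open(report_path, "w", encoding="utf-8") as fh:
        fh.write("Per-species feeding-episode tallies\n")
        fh.write(summary.to_string(index=False))
        fh.write("\n\nSeasonal one-sided chi-square tests\n")
        fh.write(seasonal.to_string(index=False) if not seasonal.empty else "(none)")
        if rmsd_frames:
            fh.write("\n\nRMSD between monitoring proportions and stomach CPs "
                     "(percentage points)\n")
            fh.write(pd.concat(rmsd_frames, ignore_index=True).to_string(index=False))
        fh.write("\n")
    artifacts["report"] = report_path
    log.write("report", f"wrote {report_path.name}")
    return artifacts


def _draws_long(results) -> pd.DataFrame:
    """Thinned posterior draws of the complete counts in long format."""
    arr = results.draws["complete_counts"]
    chains, ndraw, n_months, n_items = arr.shape
    items = results.model.data.schema.identified_items
    frames = []
    for c in range(chains):
        for d in range(ndraw):
            frame = pd.DataFrame(arr[c, d], columns=list(items))
            frame.insert(0, "month", range(1, n_months + 1))
            frame.insert(0, "draw", d)
            frame.insert(0, "chain", c)
            frames.append(frame)
    return pd.concat(frames, ignore_index=True)
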