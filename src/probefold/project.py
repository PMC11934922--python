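"""Project lifecycle: initialization, configuration, stage orchestration.

A project is a directory with ``config.yaml``, ``samples.tsv``, a
``resources/`` tree holding raw reactivity files, sequences and alignments,
and a ``results/`` tree with one folder per stage.  Every output file records
the configuration hash and seed in a header comment, and re-running a stage
with unchanged inputs and configuration reuses the existing output (staleness
is tracked by content hashes, robust to file copying).

A *condition key* combines probe and experimental condition
(``"<probe>_<condition>"``): profiles obtained with different probes are
distinct conditions for modeling.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import formats_io as fio
from .aggregate import (
    AggregatedProfile,
    ConsistencyConfig,
    aggregate_replicates,
    concatenate_primers,
    replicate_correlations,
)
from .fold_engine import EnergyModel, PseudoEnergyParams
from .footprint import FootprintConfig, footprint, footprint_outputs
from .formats_io import ClassScheme, ReactivityProfile, SENTINEL
from .predict import MsaCondition, predict_structures
from .preprocess import NormalizationConfig, preprocess_profile

STAGES = ("preprocess", "aggregate", "predict", "footprint")

_DEFAULT_CONFIG = """\
# probefold project configuration
name: {name}
seed: 42

normalization:
  method: simple          # one method per project: simple | interquartile
  simple_outlier_fraction: 0.02
  simple_norm_fraction: 0.08
  iqr_multiplier: 1.5
  iqr_norm_fraction: 0.10
  zero_floor: -0.3

consistency:
  min_std: 0.15
  min_ndata: 2

class_scheme:
  reactivity_medium: 0.4
  reactivity_high: 0.7

engine:
  m: 2.6                  # pseudo-energy slope, kcal/mol
  b: -0.8                 # pseudo-energy intercept, kcal/mol
  n_samples: 1000
  max_k: 10

footprint:
  diff_threshold: 0.2
  alpha: 0.05
  bh_correction: false

# Prediction runs: each names the condition keys ("<probe>_<condition>") it
# combines, plus an optional MSA fasta under resources/msa/.
runs: []
#  - name: pooled
#    rna: MyRNA
#    conditions: [1M7_apo, DMS_apo]
#    msa: null

# Footprint comparisons between two condition keys of one RNA.
footprints: []
#  - name: ligand
#    rna: MyRNA
#    condition1: 1M7_apo
#    condition2: 1M7_holo
"""

_SAMPLES_TEMPLATE = (
    "rna_id\tprobe\tcondition\treplicate\tprimer_start\tprimer_end\t"
    "file_path\texperimentalist\tdiscarded\n"
)


@dataclass
class ProjectConfig:
    name: str
    seed: int
    normalization: NormalizationConfig
    consistency: ConsistencyConfig
    scheme: ClassScheme
    model: EnergyModel
    pseudo_params: PseudoEnergyParams
    n_samples: int
    max_k: int
    footprint_cfg: FootprintConfig
    runs: list
    footprints: list
    raw: dict = field(default_factory=dict)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def init_project(name: str, directory) -> Path:
    """Create a project skeleton; refuses non-empty directories."""
    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()):
        raise FileExistsError(f"refusing to initialize non-empty directory {directory}")
    for sub in ("resources/raw", "resources/sequences", "resources/msa", "results"):
        (directory / sub).mkdir(parents=True, exist_ok=True)
    (directory / "config.yaml").write_text(_DEFAULT_CONFIG.format(name=name))
    (directory / "samples.tsv").write_text(_SAMPLES_TEMPLATE)
    (directory / "project.log").write_text("")
    return directory


def load_config(path) -> ProjectConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    norm = raw.get("normalization", {}) or {}
    cons = raw.get("consistency", {}) or {}
    scheme_cfg = raw.get("class_scheme", {}) or {}
    engine = raw.get("engine", {}) or {}
    fp = raw.get("footprint", {}) or {}
    scheme = ClassScheme(
        reactivity_medium=float(scheme_cfg.get("reactivity_medium", 0.4)),
        reactivity_high=float(scheme_cfg.get("reactivity_high", 0.7)),
    )
    cfg = ProjectConfig(
        name=str(raw.get("name", "project")),
        seed=int(raw.get("seed", 42)),
        normalization=NormalizationConfig(
            method=str(norm.get("method", "simple")),
            simple_outlier_fraction=float(norm.get("simple_outlier_fraction", 0.02)),
            simple_norm_fraction=float(norm.get("simple_norm_fraction", 0.08)),
            iqr_multiplier=float(norm.get("iqr_multiplier", 1.5)),
            iqr_norm_fraction=float(norm.get("iqr_norm_fraction", 0.10)),
            zero_floor=float(norm.get("zero_floor", -0.3)),
        ),
        consistency=ConsistencyConfig(
            min_std=float(cons.get("min_std", 0.15)),
            min_ndata=int(cons.get("min_ndata", 2)),
            scheme=scheme,
        ),
        scheme=scheme,
        model=EnergyModel(),
        pseudo_params=PseudoEnergyParams(
            m=float(engine.get("m", 2.6)), b=float(engine.get("b", -0.8))
        ),
        n_samples=int(engine.get("n_samples", 1000)),
        max_k=int(engine.get("max_k", 10)),
        footprint_cfg=FootprintConfig(
            diff_threshold=float(fp.get("diff_threshold", 0.2)),
            alpha=float(fp.get("alpha", 0.05)),
            bh_correction=bool(fp.get("bh_correction", False)),
        ),
        runs=list(raw.get("runs") or []),
        footprints=list(raw.get("footprints") or []),
        raw=raw,
    )
    for run in cfg.runs:
        if "name" not in run or "rna" not in run or not run.get("conditions"):
            raise ValueError(f"invalid prediction run entry: {run}")
    for comp in cfg.footprints:
        for key in ("name", "rna", "condition1", "condition2"):
            if key not in comp:
                raise ValueError(f"invalid footprint entry: {comp}")
    return cfg


def _file_sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:12]


def _header_fields(path: Path) -> dict:
    fields = {}
    with path.open() as handle:
        for line in handle:
            if not line.startswith("#"):
                break
            for token in line[1:].split():
                if "=" in token:
                    key, value = token.split("=", 1)
                    fields[key] = value
    return fields


def _log(project: Path, message: str) -> None:
    with (project / "project.log").open("a") as handle:
        handle.write(f"{time.strftime('%Y-%m-%dT%H:%M:%S')}\t{message}\n")


def _condition_key(probe: str, condition: str) -> str:
    return f"{probe}_{condition}"


def _read_sequence(project: Path, rna_id: str) -> Optional[str]:
    for ext in (".fa", ".fas", ".fasta"):
        path = project / "resources" / "sequences" / f"{rna_id}{ext}"
        if path.exists():
            return next(iter(fio.read_fasta_sequences(path).values()))
    return None


class Project:
    """Handle on a project directory with stage-wise execution."""

    def __init__(self, directory):
        self.dir = Path(directory)
        config_path = self.dir / "config.yaml"
        if not config_path.exists():
            raise FileNotFoundError(f"missing config file {config_path}")
        self.config = load_config(config_path)
        samples_path = self.dir / "samples.tsv"
        if not samples_path.exists():
            raise FileNotFoundError(f"missing samples table {samples_path}")
        self.samples = fio.read_samples_table(samples_path)

    # -- stage: preprocess ---------------------------------------------------

    def _preprocess_name(self, row) -> str:
        return (
            f"{row.rna_id}_{row.probe}_{row.condition}_{row.replicate}"
            f"_{row.primer_start}-{row.primer_end}.tsv"
        )

    def run_preprocess(self, seed: Optional[int] = None) -> list[Path]:
        out_dir = self.dir / "results" / "preprocess"
        out_dir.mkdir(parents=True, exist_ok=True)
        cfg_hash = self.config.config_hash
        outputs = []
        for row in self.samples.active().itertuples(index=False):
            raw_path = self.dir / row.file_path
            if not raw_path.exists():
                raise FileNotFoundError(
                    f"preprocess: missing reactivity file {raw_path} "
                    f"(sample {row.rna_id}/{row.probe}/{row.condition}/{row.replicate})"
                )
            out_path = out_dir / self._preprocess_name(row)
            input_sha = _file_sha(raw_path)
            if out_path.exists():
                fields = _header_fields(out_path)
                if fields.get("config") == cfg_hash and fields.get("input") == input_sha:
                    outputs.append(out_path)
                    continue
            profile = fio.read_reactivity_tsv(
                raw_path,
                rna_id=row.rna_id,
                condition_id=_condition_key(row.probe, row.condition),
                replicate_id=str(row.replicate),
            )
            processed = preprocess_profile(profile, self.config.normalization)
            fio.write_reactivity_tsv(
                processed, out_path, header=f"config={cfg_hash} input={input_sha}"
            )
            outputs.append(out_path)
        _log(self.dir, f"preprocess\tconfig={cfg_hash}\tfiles={len(outputs)}")
        return outputs

    def _load_preprocessed(self):
        """Preprocessed profiles grouped by (rna, condition key, primer
        range), then replicate."""
        out_dir = self.dir / "results" / "preprocess"
        grouped: dict = {}
        for row in self.samples.active().itertuples(index=False):
            path = out_dir / self._preprocess_name(row)
            if not path.exists():
                raise FileNotFoundError(
                    f"aggregate: expected preprocessed file {path}; run the "
                    "preprocess stage first"
                )
            key = (row.rna_id, _condition_key(row.probe, row.condition))
            segment = (int(row.primer_start), int(row.primer_end))
            profile = fio.read_reactivity_tsv(
                path, rna_id=row.rna_id, condition_id=key[1], replicate_id=str(row.replicate)
            )
            grouped.setdefault(key, {}).setdefault(segment, []).append(profile)
        return grouped

    # -- stage: aggregate ----------------------------------------------------

    def run_aggregate(self, seed: Optional[int] = None) -> list[Path]:
        out_dir = self.dir / "results" / "aggregate"
        out_dir.mkdir(parents=True, exist_ok=True)
        cfg_hash = self.config.config_hash
        grouped = self._load_preprocessed()
        outputs = []
        for (rna_id, key), segments in sorted(grouped.items()):
            seg_aggregates = []
            for (start, end), replicates in sorted(segments.items()):
                trimmed = [
                    p.copy_with(_segment_values(p.values, start, end)) for p in replicates
                ]
                agg = aggregate_replicates(trimmed, self.config.consistency)
                seg_aggregates.append((agg, start, end))
                if len(replicates) >= 2:
                    corr = replicate_correlations(trimmed)
                    corr_path = out_dir / f"{rna_id}_{key}_{start}-{end}_correlations.tsv"
                    with corr_path.open("w") as handle:
                        handle.write(f"# config={cfg_hash}\n")
                        corr.to_csv(handle, sep="\t", index=False, float_format="%.6g")
                    outputs.append(corr_path)
            sequence = _read_sequence(self.dir, rna_id)
            rna_length = len(sequence) if sequence else None
            merged = concatenate_primers(seg_aggregates, rna_length=rna_length)
            agg_path = out_dir / f"{rna_id}_{key}.tsv"
            fio.write_aggregated_tsv(merged, agg_path, header=f"config={cfg_hash}")
            outputs.append(agg_path)
        _log(self.dir, f"aggregate\tconfig={cfg_hash}\tfiles={len(outputs)}")
        return outputs

    def _load_aggregated(self, rna_id: str, key: str) -> AggregatedProfile:
        path = self.dir / "results" / "aggregate" / f"{rna_id}_{key}.tsv"
        if not path.exists():
            raise FileNotFoundError(
                f"predict: expected aggregated profile {path}; run the "
                "aggregate stage first"
            )
        return fio.read_aggregated_tsv(path, rna_id=rna_id, condition_id=key)

    # -- stage: predict ------------------------------------------------------

    def run_predict(self, seed: Optional[int] = None, run_name: Optional[str] = None) -> list[Path]:
        cfg = self.config
        cfg_hash = cfg.config_hash
        master_seed = cfg.seed if seed is None else seed
        outputs = []
        runs = [r for r in cfg.runs if run_name in (None, r["name"])]
        if run_name is not None and not runs:
            raise ValueError(f"unknown prediction run {run_name!r}")
        for run in runs:
            rna_id = run["rna"]
            sequence = _read_sequence(self.dir, rna_id)
            if sequence is None:
                raise FileNotFoundError(
                    f"predict: expected sequence FASTA resources/sequences/{rna_id}.fa"
                )
            conditions: dict = {}
            for key in run["conditions"]:
                conditions[key] = self._load_aggregated(rna_id, key)
            if run.get("msa"):
                msa_path = self.dir / run["msa"]
                if not msa_path.exists():
                    raise FileNotFoundError(f"predict: expected MSA file {msa_path}")
                conditions["msa"] = MsaCondition(fio.read_msa_fasta(msa_path))
            result = predict_structures(
                conditions,
                sequence,
                n_samples=cfg.n_samples,
                model=cfg.model,
                pseudo_params=cfg.pseudo_params,
                max_k=cfg.max_k,
                seed=master_seed,
            )
            out_dir = self.dir / "results" / "predict" / run["name"]
            out_dir.mkdir(parents=True, exist_ok=True)
            fio.write_dotbracket(result.best, out_dir / "best.dbn", name=f"{rna_id}_best")
            outputs.append(out_dir / "best.dbn")
            if result.second is not None:
                fio.write_dotbracket(
                    result.second, out_dir / "second.dbn", name=f"{rna_id}_second"
                )
                outputs.append(out_dir / "second.dbn")
            clusters_path = out_dir / "clusters.tsv"
            with clusters_path.open("w") as handle:
                handle.write(f"# config={cfg_hash} seed={master_seed}\n")
                conds = result.condition_ids
                handle.write(
                    "cluster\tsize\tscore\t"
                    + "\t".join(f"occupancy_{c}" for c in conds)
                    + "\tcentroid\n"
                )
                for rank, cluster in enumerate(result.clusters, start=1):
                    occ = "\t".join(
                        fio._fmt(cluster.occupancy.get(c, 0.0)) for c in conds
                    )
                    handle.write(
                        f"{rank}\t{cluster.size}\t{fio._fmt(cluster.score)}\t{occ}\t"
                        f"{cluster.centroid.to_dotbracket()}\n"
                    )
            outputs.append(clusters_path)
            for key, cond in conditions.items():
                if isinstance(cond, MsaCondition):
                    continue
                color_path = out_dir / f"colors_{key}.tsv"
                fio.write_color_annotation(cond.mean, cfg.scheme, color_path)
                outputs.append(color_path)
        _log(self.dir, f"predict\tconfig={cfg_hash}\tseed={master_seed}\truns={len(runs)}")
        return outputs

    # -- stage: footprint ----------------------------------------------------

    def _replicate_profiles(self, rna_id: str, key: str) -> list[ReactivityProfile]:
        """Full-length preprocessed replicate profiles for one condition
        key (primer segments of the same replicate merged)."""
        grouped = self._load_preprocessed()
        if (rna_id, key) not in grouped:
            raise FileNotFoundError(
                f"footprint: no preprocessed data for {rna_id} / {key}"
            )
        segments = grouped[(rna_id, key)]
        sequence = _read_sequence(self.dir, rna_id)
        length = len(sequence) if sequence else max(end for _, end in segments)
        by_replicate: dict = {}
        for (start, end), replicates in sorted(segments.items()):
            for profile in replicates:
                values = by_replicate.setdefault(
                    profile.replicate_id, np.full(length, SENTINEL)
                )
                seg_vals = _segment_values(profile.values, start, end)
                for offset, value in enumerate(seg_vals):
                    pos = start - 1 + offset
                    if value == SENTINEL:
                        continue
                    if values[pos] == SENTINEL:
                        values[pos] = value
                    else:
                        values[pos] = (values[pos] + value) / 2.0
        return [
            ReactivityProfile(rna_id, key, rep, values)
            for rep, values in sorted(by_replicate.items())
        ]

    def run_footprint(self, seed: Optional[int] = None) -> list[Path]:
        cfg = self.config
        cfg_hash = cfg.config_hash
        outputs = []
        for comp in cfg.footprints:
            rna_id = comp["rna"]
            cond1 = self._replicate_profiles(rna_id, comp["condition1"])
            cond2 = self._replicate_profiles(rna_id, comp["condition2"])
            records = footprint(cond1, cond2, cfg.footprint_cfg)
            out_dir = self.dir / "results" / "footprint" / comp["name"]
            structure = None
            dbn = comp.get("structure")
            if dbn:
                structure = fio.read_dotbracket(self.dir / dbn)
            paths = footprint_outputs(
                records, out_dir, structure=structure, header=f"config={cfg_hash}"
            )
            outputs.extend(paths.values())
        _log(self.dir, f"footprint\tconfig={cfg_hash}\tcomparisons={len(cfg.footprints)}")
        return outputs

    # -- orchestration -------------------------------------------------------

    def run(self, stages=None, seed: Optional[int] = None) -> dict:
        stages = list(stages) if stages else list(STAGES)
        unknown = set(stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        results = {}
        for stage in STAGES:
            if stage not in stages:
                continue
            if stage == "predict" and not self.config.runs:
                continue
            if stage == "footprint" and not self.config.footprints:
                continue
            runner = getattr(self, f"run_{stage}")
            results[stage] = runner(seed=seed)
        return results


def _segment_values(values: np.ndarray, start: int, end: int) -> np.ndarray:
    """Extract 1-based ``start..end`` from a profile, sentinel-padding when
    the file is shorter than the primer range."""
    length = end - start + 1
    out = np.full(length, SENTINEL)
    hi = min(end, values.size)
    if hi >= start:
        out[: hi - start + 1] = values[start - 1: hi]
    return out


def run_pipeline(project_dir, stages=None, seed: Optional[int] = None) -> dict:
    """Load a project directory and execute the requested stages in order."""
    return Project(project_dir).run(stages=stages, seed=seed)
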