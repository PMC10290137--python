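"""End-to-end orchestration of the analysis stages.

A single structured config (YAML or JSON) drives the run:
grade -> merge PPI -> network -> co-occurrence -> enrichment, optionally
preceded by a simulation stage that generates every input with known
ground truth. Each stage communicates with the next only through its
serialized output files, every produced file is checksummed into a run
manifest, and identical config + seeds reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from epinet.errors import ConfigError, StageError
from epinet import grading, ppi, network, cooccurrence, enrichment, simulate

__all__ = ["PipelineConfig", "validate_config", "run_pipeline"]

logger = logging.getLogger(__name__)

_INPUT_KEYS = (
    "esc", "samples", "detections", "ppi_biogrid", "ppi_mitab",
    "orthologs", "chaperome", "gmt",
)
_OPTIONAL_INPUT_KEYS = ("hierarchy", "background")


@dataclass
class PipelineConfig:
    outdir: Path
    inputs: dict[str, Path] = field(default_factory=dict)
    simulate: dict | None = None
    welch: bool = False
    grade_filter: tuple[str, ...] = ("A", "B")
    n_sims: int = 100_000
    cooccur_seed: int = 7
    add_one: bool = False
    weighted_topology: bool = False

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        d["outdir"] = str(self.outdir)
        d["inputs"] = {k: str(v) for k, v in self.inputs.items()}
        d["grade_filter"] = list(self.grade_filter)
        return d


def _load_raw(path: str | Path) -> dict:
    text = Path(path).read_text()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"unparseable config file {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    return raw


def collect_violations(raw: dict, base_dir: Path) -> list[str]:
    """All config violations at once (never fail-fast on the first)."""
    violations: list[str] = []
    has_sim = isinstance(raw.get("simulate"), dict)
    inputs = raw.get("inputs") or {}
    if not has_sim:
        for key in _INPUT_KEYS:
            if key not in inputs:
                violations.append(f"inputs.{key}: missing required input path")
            elif not (base_dir / inputs[key]).exists():
                violations.append(f"inputs.{key}: file not found: {inputs[key]}")
    for key in _OPTIONAL_INPUT_KEYS:
        if key in inputs and not (base_dir / inputs[key]).exists():
            violations.append(f"inputs.{key}: file not found: {inputs[key]}")
    if "outdir" not in raw:
        violations.append("outdir: missing output directory")
    cooccur = raw.get("cooccur") or {}
    n_sims = cooccur.get("n_sims", 100_000)
    if not isinstance(n_sims, int) or n_sims < 1:
        violations.append(
            "cooccur.n_sims: must be an integer >= 1 "
            "(the co-occurrence test requires at least one simulation)"
        )
    seed = cooccur.get("seed", 7)
    if not isinstance(seed, int):
        violations.append("cooccur.seed: must be an integer")
    grade = raw.get("grade") or {}
    gf = grade.get("grade_filter", ["A", "B"])
    bad = set(gf) - set(grading.GRADES)
    if bad:
        violations.append(f"grade.grade_filter: unknown grades {sorted(bad)}")
    if has_sim:
        sim = raw["simulate"]
        for section, cls in (
            ("esc", simulate.EscSimConfig),
            ("dual_bait", simulate.DualBaitSimConfig),
            ("ppi", simulate.PpiSimConfig),
        ):
            params = sim.get(section, {}) or {}
            try:
                cls(**params).validate()
            except (TypeError, ConfigError) as exc:
                violations.append(f"simulate.{section}: {exc}")
    return violations


def validate_config(path: str | Path) -> PipelineConfig:
    """Load and fully validate a pipeline config file.

    Raises :class:`ConfigError` listing every violation found; otherwise
    returns the resolved config (paths resolved against the config file's
    directory).
    """
    path = Path(path)
    raw = _load_raw(path)
    base_dir = path.parent
    violations = collect_violations(raw, base_dir)
    if violations:
        raise ConfigError(
            "invalid pipeline config:\n  - " + "\n  - ".join(violations)
        )
    inputs = {
        k: (base_dir / v) for k, v in (raw.get("inputs") or {}).items()
    }
    grade = raw.get("grade") or {}
    cooccur = raw.get("cooccur") or {}
    net = raw.get("network") or {}
    return PipelineConfig(
        outdir=base_dir / raw["outdir"],
        inputs=inputs,
        simulate=raw.get("simulate"),
        welch=bool(grade.get("welch", False)),
        grade_filter=tuple(grade.get("grade_filter", ["A", "B"])),
        n_sims=int(cooccur.get("n_sims", 100_000)),
        cooccur_seed=int(cooccur.get("seed", 7)),
        add_one=bool(cooccur.get("add_one", False)),
        weighted_topology=bool(net.get("weighted_topology", False)),
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage(manifest: dict, name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            manifest["stages"][name] = {"seconds": round(dt, 3)}
            if exc is not None and not isinstance(exc, StageError):
                raise StageError(name, str(exc)) from exc
            logger.info("stage %s: done (%.2fs)", name, dt)
            return False

    return _Timer()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages in dependency order and return the manifest.

    The manifest (also written as ``manifest.json`` in the output
    directory) records the tool version, an echo of the config, per-stage
    wall-clock, warnings, and a sha256 checksum for every produced file.
    """
    from epinet import __version__

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "epinet",
        "version": __version__,
        "config": config.echo(),
        "stages": {},
        "files": {},
        "warnings": [],
    }
    produced: dict[str, Path] = {}
    inputs = dict(config.inputs)

    # --- stage 0: simulate (optional) ------------------------------------
    if config.simulate is not None:
        with _stage(manifest, "simulate"):
            fixture_dir = outdir / "fixture"
            sim = config.simulate
            esc_cfg = simulate.EscSimConfig(**(sim.get("esc") or {}))
            table, esc_truth = simulate.generate_esc_table(esc_cfg)
            paths = simulate.write_esc_files(table, fixture_dir)
            esc_truth.to_json(fixture_dir / "ground_truth_esc.json")

            db_cfg = simulate.DualBaitSimConfig(**(sim.get("dual_bait") or {}))
            det, det_truth = simulate.generate_dual_bait_detections(db_cfg)
            det_path = simulate.write_detection_file(det, fixture_dir / "detections.tsv")
            det_truth.to_json(fixture_dir / "ground_truth_detections.json")

            ppi_cfg = simulate.PpiSimConfig(**(sim.get("ppi") or {}))
            # PPI fixture shares the ESC protein namespace; planted true
            # interactors come first so the chaperome core is bait-detected
            truths = sorted(esc_truth.true_interactor_ids)
            others = [p for p in table.protein_ids if p not in esc_truth.true_interactor_ids]
            ppi_paths, _ = simulate.generate_ppi_fixture(
                ppi_cfg, fixture_dir, node_ids=truths + others
            )
            inputs.update(
                esc=paths["esc"], samples=paths["samples"], detections=det_path,
                ppi_biogrid=ppi_paths["biogrid"], ppi_mitab=ppi_paths["mitab"],
                orthologs=ppi_paths["orthologs"], chaperome=ppi_paths["chaperome"],
                gmt=ppi_paths["gmt"],
            )
            for p in fixture_dir.iterdir():
                produced[f"fixture/{p.name}"] = p

    # --- stage 1: grade ---------------------------------------------------
    with _stage(manifest, "grade"):
        table = grading.SpectralCountTable.from_files(inputs["esc"], inputs["samples"])
        graded = grading.grade_interactors(table, welch=config.welch)
        grade_paths = grading.write_graded(graded, outdir)
        produced["graded_interactors.tsv"] = grade_paths["graded"]
        produced["grade_summary.json"] = grade_paths["summary"]
        summary = grading.summarize_grades(graded)
        if summary["total_excluded"]:
            manifest["warnings"].append(
                f"grade: {summary['total_excluded']} control-dominant proteins excluded"
            )

    # --- stage 2: merge PPI -----------------------------------------------
    with _stage(manifest, "mergeppi"):
        bg = ppi.read_biogrid_tab(inputs["ppi_biogrid"])
        mt = ppi.read_mitab(inputs["ppi_mitab"])
        orthologs = ppi.read_orthologs(inputs["orthologs"])
        mapped_bg, unmapped_bg = ppi.map_to_human(bg.records, orthologs)
        mapped_mt, unmapped_mt = ppi.map_to_human(mt.records, orthologs)
        db = ppi.merge(mapped_bg, mapped_mt)
        merged_path = outdir / "merged_ppi.tsv"
        db.to_tsv(merged_path)
        produced["merged_ppi.tsv"] = merged_path

        unmapped_path = outdir / "unmapped.tsv"
        rows = ["source\traw_line_no\tid_a\tid_b\ttaxon_a\ttaxon_b"]
        for rec in unmapped_bg + unmapped_mt:
            rows.append(
                f"{rec.source}\t{rec.raw_line_no}\t{rec.id_a}\t{rec.id_b}"
                f"\t{rec.taxon_a}\t{rec.taxon_b}"
            )
        unmapped_path.write_text("\n".join(rows) + "\n")
        produced["unmapped.tsv"] = unmapped_path

        rejects_path = outdir / "rejects.tsv"
        rows = ["file\tline_no\treason"]
        for name, res in (("ppi_biogrid", bg), ("ppi_mitab", mt)):
            for rej in res.rejects:
                rows.append(f"{name}\t{rej.line_no}\t{rej.reason}")
        rejects_path.write_text("\n".join(rows) + "\n")
        produced["rejects.tsv"] = rejects_path
        n_drop = len(unmapped_bg) + len(unmapped_mt)
        if n_drop:
            manifest["warnings"].append(
                f"mergeppi: {n_drop} records dropped (no human ortholog)"
            )
        if bg.rejects or mt.rejects:
            manifest["warnings"].append(
                f"mergeppi: {len(bg.rejects) + len(mt.rejects)} malformed lines rejected"
            )

    # --- stage 3: network -------------------------------------------------
    # downstream stages consume only the serialized outputs of earlier ones
    with _stage(manifest, "network"):
        db = ppi.MergedPPIDatabase.from_tsv(produced["merged_ppi.tsv"])
        graded = grading.read_graded(produced["graded_interactors.tsv"])
        chaperome = {
            line.strip()
            for line in Path(inputs["chaperome"]).read_text().splitlines()
            if line.strip()
        }
        keep = graded[graded["grade"].isin(config.grade_filter)]
        detected = {
            pid: {"detected_by": ["epiHSP70_bait"], "grade": row["grade"]}
            for pid, row in keep.iterrows()
        }
        net = network.build_network(db, detected, chaperome)
        network.assign_edge_weights(net)
        produced["network.graphml"] = network.export_graph(
            net, outdir / "network.graphml", "graphml"
        )
        produced["network_edges.tsv"] = network.export_graph(
            net, outdir / "network_edges.tsv", "tsv_edgelist"
        )
        topo = network.compute_topology(net, weighted=config.weighted_topology)
        topo_path = outdir / "topology.json"
        topo_path.write_text(json.dumps(topo, indent=1, sort_keys=True) + "\n")
        produced["topology.json"] = topo_path
        n_isolates = sum(1 for v in net.nodes if net.degree(v) == 0)
        if n_isolates:
            manifest["warnings"].append(f"network: {n_isolates} isolate nodes")

    # --- stage 4: co-occurrence -------------------------------------------
    with _stage(manifest, "cooccur"):
        det = pd.read_csv(inputs["detections"], sep="\t", index_col=0).astype(bool)
        res = cooccurrence.test_cooccurrence(
            det,
            n_sims=config.n_sims,
            seed=config.cooccur_seed,
            add_one=config.add_one,
        )
        cooccur_path = outdir / "cooccurrence.json"
        cooccur_path.write_text(json.dumps(res.to_dict(), indent=1, sort_keys=True) + "\n")
        produced["cooccurrence.json"] = cooccur_path

    # --- stage 5: enrichment ----------------------------------------------
    with _stage(manifest, "enrich"):
        coll = enrichment.read_gmt(inputs["gmt"])
        if "hierarchy" in inputs:
            coll.hierarchy = enrichment.read_hierarchy(inputs["hierarchy"])
        background = None
        if "background" in inputs:
            background = {
                line.strip()
                for line in Path(inputs["background"]).read_text().splitlines()
                if line.strip()
            }
        query = set(keep.index)
        results = enrichment.enrich(query, coll, background)
        enr_path = outdir / "enrichment.tsv"
        results.to_csv(enr_path, sep="\t", index=False, float_format="%.12g")
        produced["enrichment.tsv"] = enr_path
        tree = enrichment.hierarchy_rollup(results, coll)
        tree_path = outdir / "enrichment_tree.json"
        tree_path.write_text(json.dumps(tree, indent=1, sort_keys=True) + "\n")
        produced["enrichment_tree.json"] = tree_path
        if coll.rejected:
            manifest["warnings"].append(
                f"enrich: {len(coll.rejected)} empty gene sets rejected"
            )

    for name, p in sorted(produced.items()):
        manifest["files"][name] = _sha256(Path(p))
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest
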