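"""Synthetic data with known ground truth for every pipeline input.

Three generators cover the three kinds of input the pipeline consumes:

* :func:`generate_esc_table` — an exclusive-spectral-count (ESC) matrix with
  bait and control replicates, planted true interactors (bait-enriched) and
  background contaminants. Counts are Poisson by default, negative binomial
  when over-dispersion is requested, with independent per-cell detection
  dropout applied after the draw.
* :func:`generate_dual_bait_detections` — paired Bernoulli detection
  indicators for two baits with a tunable target correlation, constructed as
  a mixture of the independence table and the appropriate Fréchet bound so
  the joint 2x2 cell probabilities are available in closed form.
* :func:`generate_ppi_fixture` — a small multi-species PPI database split
  across a BioGRID-tab-like file and a MITAB-2.5-like file (with overlapping
  edges, so merging and deduplication are exercised), an ortholog table with
  tunable missingness, a chaperome membership list, and a GMT gene-set
  collection with one set planted to be enriched among chaperome-adjacent
  nodes.

All generators are deterministic functions of their config (including the
seed): the same config yields byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from epinet.errors import ConfigError
from epinet.grading import SpectralCountTable

__all__ = [
    "EscSimConfig",
    "DualBaitSimConfig",
    "PpiSimConfig",
    "GroundTruth",
    "generate_esc_table",
    "generate_dual_bait_detections",
    "generate_ppi_fixture",
    "dual_bait_joint_table",
    "write_esc_files",
    "write_detection_file",
]


# ---------------------------------------------------------------------------
# configs


def _check(cond: bool, fieldname: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"invalid config field '{fieldname}': {msg}")


@dataclass(frozen=True)
class EscSimConfig:
    """Parameters of the spectral-count simulation.

    ``background_mean`` is the expected ESC of a non-interactor in any
    sample; planted true interactors have mean
    ``enrichment_factor * background_mean`` in bait samples and
    ``background_mean`` in control samples. ``dispersion`` switches the
    count model from Poisson (None) to negative binomial with that size
    parameter (smaller = more over-dispersed).
    """

    n_proteins: int = 1000
    n_true_interactors: int = 100
    n_bait_reps: int = 3
    n_control_reps: int = 3
    background_mean: float = 3.0
    enrichment_factor: float = 10.0
    detect_dropout: float = 0.05
    dispersion: float | None = None
    seed: int = 0

    def validate(self) -> None:
        _check(self.n_proteins >= 0, "n_proteins", "must be >= 0")
        _check(
            0 <= self.n_true_interactors <= self.n_proteins,
            "n_true_interactors",
            "must be between 0 and n_proteins",
        )
        _check(self.n_bait_reps >= 2, "n_bait_reps", "must be >= 2")
        _check(self.n_control_reps >= 2, "n_control_reps", "must be >= 2")
        _check(self.background_mean > 0, "background_mean", "must be > 0")
        _check(self.enrichment_factor >= 1, "enrichment_factor", "must be >= 1")
        _check(0 <= self.detect_dropout <= 1, "detect_dropout", "must be in [0, 1]")
        if self.dispersion is not None:
            _check(self.dispersion > 0, "dispersion", "must be > 0 when set")


@dataclass(frozen=True)
class DualBaitSimConfig:
    """Parameters of the paired-detection simulation.

    ``dependence`` is the target Pearson correlation between the two
    detection indicators; it must lie inside the Fréchet-achievable
    correlation interval implied by the two prevalences.
    """

    n_interactors: int = 5704
    prevalence_a: float = 0.5
    prevalence_b: float = 0.5
    dependence: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        _check(self.n_interactors >= 0, "n_interactors", "must be >= 0")
        _check(0 <= self.prevalence_a <= 1, "prevalence_a", "must be in [0, 1]")
        _check(0 <= self.prevalence_b <= 1, "prevalence_b", "must be in [0, 1]")
        _check(-1 <= self.dependence <= 1, "dependence", "must be in [-1, 1]")
        # achievability is checked (with the exact interval) in
        # dual_bait_joint_table, which needs the marginals
        dual_bait_joint_table(self.prevalence_a, self.prevalence_b, self.dependence)


@dataclass(frozen=True)
class PpiSimConfig:
    """Parameters of the PPI database fixture.

    Nodes are protein symbols; the first ``n_chaperome`` form the chaperome
    core. Edge probability depends on the pair's layer: core-core,
    core-other (shell) or other-other (outer). Each edge is attributed to a
    taxon from ``taxa``; non-human records appear in the ortholog table
    except with probability ``ortholog_noise`` per foreign identifier.
    """

    n_nodes: int = 50
    n_chaperome: int = 8
    edge_prob_core: float = 0.8
    edge_prob_shell: float = 0.25
    edge_prob_outer: float = 0.05
    taxa: tuple[int, ...] = (9606, 10090, 559292)
    ortholog_noise: float = 0.0
    n_decoy_genesets: int = 5
    seed: int = 0

    def validate(self) -> None:
        _check(self.n_nodes >= 0, "n_nodes", "must be >= 0")
        _check(
            0 <= self.n_chaperome <= self.n_nodes,
            "n_chaperome",
            "must be between 0 and n_nodes",
        )
        for name in ("edge_prob_core", "edge_prob_shell", "edge_prob_outer", "ortholog_noise"):
            _check(0 <= getattr(self, name) <= 1, name, "must be in [0, 1]")
        _check(len(self.taxa) >= 1, "taxa", "must list at least one taxon")
        _check(all(t > 0 for t in self.taxa), "taxa", "taxon IDs must be positive")
        _check(self.n_decoy_genesets >= 0, "n_decoy_genesets", "must be >= 0")


@dataclass
class GroundTruth:
    """Everything planted by a generator, sufficient to score recovery."""

    true_interactor_ids: set[str] = field(default_factory=set)
    chaperome_ids: set[str] = field(default_factory=set)
    planted_enriched_set: str | None = None
    planted_set_members: set[str] = field(default_factory=set)
    dual_bait_joint_probabilities: list[list[float]] | None = None
    merged_human_edges: set[tuple[str, str]] | None = None
    unmapped_source_ids: set[str] = field(default_factory=set)
    extra: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        def _enc(v):
            if isinstance(v, set):
                return sorted(sorted(e) if isinstance(e, tuple) else e for e in v)
            return v

        payload = {k: _enc(v) for k, v in dataclasses.asdict(self).items()}
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        raw = json.loads(Path(path).read_text())
        gt = cls()
        for k, v in raw.items():
            if k in ("true_interactor_ids", "chaperome_ids", "planted_set_members",
                     "unmapped_source_ids"):
                setattr(gt, k, set(v))
            elif k == "merged_human_edges":
                setattr(gt, k, None if v is None else {tuple(e) for e in v})
            else:
                setattr(gt, k, v)
        return gt


# ---------------------------------------------------------------------------
# ESC tables


def generate_esc_table(cfg: EscSimConfig) -> tuple[SpectralCountTable, GroundTruth]:
    """Draw an ESC matrix (proteins x samples) with planted interactors.

    Returns the count table plus a :class:`GroundTruth` listing the planted
    true-interactor IDs. Deterministic under ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    n = cfg.n_proteins
    protein_ids = [f"P{i:05d}" for i in range(n)]
    bait_ids = [f"bait_{i + 1}" for i in range(cfg.n_bait_reps)]
    ctrl_ids = [f"control_{i + 1}" for i in range(cfg.n_control_reps)]
    sample_ids = bait_ids + ctrl_ids
    roles = pd.Series(
        ["bait"] * cfg.n_bait_reps + ["control"] * cfg.n_control_reps,
        index=sample_ids,
        name="role",
    )

    if n == 0:
        counts = pd.DataFrame(
            np.zeros((0, len(sample_ids)), dtype=np.int64),
            index=pd.Index(protein_ids, name="protein_id"),
            columns=sample_ids,
        )
        return SpectralCountTable(counts, roles), GroundTruth()

    true_idx = rng.choice(n, size=cfg.n_true_interactors, replace=False)
    means = np.full((n, len(sample_ids)), cfg.background_mean, dtype=float)
    means[np.ix_(true_idx, np.arange(cfg.n_bait_reps))] = (
        cfg.enrichment_factor * cfg.background_mean
    )

    if cfg.dispersion is None:
        counts = rng.poisson(means)
    else:
        # NB with mean mu, size r: p = r / (r + mu)
        r = cfg.dispersion
        counts = rng.negative_binomial(r, r / (r + means))
    if cfg.detect_dropout > 0:
        counts = np.where(rng.random(means.shape) < cfg.detect_dropout, 0, counts)

    table = SpectralCountTable(
        pd.DataFrame(
            counts.astype(np.int64),
            index=pd.Index(protein_ids, name="protein_id"),
            columns=sample_ids,
        ),
        roles,
    )
    truth = GroundTruth(
        true_interactor_ids={protein_ids[i] for i in true_idx},
    )
    return table, truth


def write_esc_files(table: SpectralCountTable, outdir: str | Path) -> dict[str, Path]:
    """Serialize an ESC table as ``esc_table.tsv`` + ``samples.tsv``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    esc_path = outdir / "esc_table.tsv"
    samples_path = outdir / "samples.tsv"
    table.to_files(esc_path, samples_path)
    return {"esc": esc_path, "samples": samples_path}


# ---------------------------------------------------------------------------
# dual-bait detections


def dual_bait_joint_table(p_a: float, p_b: float, dependence: float) -> np.ndarray:
    """Closed-form 2x2 joint cell probabilities for the paired detections.

    Rows index bait A (absent, present), columns bait B. The construction
    interpolates linearly between the independence table and the Fréchet
    upper (comonotone) or lower (countermonotone) bound, with the mixture
    weight chosen so that the Pearson correlation of the two indicators
    equals ``dependence`` exactly; equivalently
    ``P(both) = p_a p_b + dependence * sqrt(p_a q_a p_b q_b)``.

    Raises :class:`ConfigError` stating the achievable correlation interval
    when ``dependence`` lies outside it.
    """
    for name, p in (("prevalence_a", p_a), ("prevalence_b", p_b)):
        _check(0 <= p <= 1, name, "must be in [0, 1]")
    q_a, q_b = 1 - p_a, 1 - p_b
    denom = np.sqrt(p_a * q_a * p_b * q_b)
    if denom == 0:
        # a degenerate marginal admits only zero correlation
        _check(dependence == 0, "dependence",
               "must be 0 when a prevalence is 0 or 1 (achievable interval [0, 0])")
        p11 = p_a * p_b
    else:
        upper = (min(p_a, p_b) - p_a * p_b) / denom
        lower = (max(0.0, p_a + p_b - 1) - p_a * p_b) / denom
        _check(
            lower - 1e-12 <= dependence <= upper + 1e-12,
            "dependence",
            f"target correlation outside the Fréchet-achievable interval "
            f"[{lower:.6f}, {upper:.6f}] for prevalences ({p_a}, {p_b})",
        )
        p11 = p_a * p_b + dependence * denom
    p10 = p_a - p11
    p01 = p_b - p11
    p00 = 1.0 - p11 - p10 - p01
    table = np.array([[p00, p01], [p10, p11]])
    return np.clip(table, 0.0, 1.0)


def generate_dual_bait_detections(
    cfg: DualBaitSimConfig,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw paired detection indicators for two baits.

    Returns a DataFrame indexed by protein ID with boolean columns
    ``bait_a`` and ``bait_b``, and the ground truth carrying the exact joint
    cell probabilities. With ``dependence=0`` the two columns are drawn
    independently.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    joint = dual_bait_joint_table(cfg.prevalence_a, cfg.prevalence_b, cfg.dependence)

    n = cfg.n_interactors
    if cfg.dependence == 0:
        a = rng.random(n) < cfg.prevalence_a
        b = rng.random(n) < cfg.prevalence_b
    else:
        cells = rng.choice(4, size=n, p=joint.ravel())
        a = cells >= 2  # rows of the 2x2: index 2,3 have A present
        b = (cells % 2) == 1
    det = pd.DataFrame(
        {"bait_a": a, "bait_b": b},
        index=pd.Index([f"P{i:05d}" for i in range(n)], name="protein_id"),
    )
    truth = GroundTruth(dual_bait_joint_probabilities=joint.tolist())
    return det, truth


def write_detection_file(det: pd.DataFrame, path: str | Path) -> Path:
    """Serialize detections as TSV with 0/1 columns."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    det.astype(int).to_csv(path, sep="\t")
    return path


# ---------------------------------------------------------------------------
# PPI fixture

_MITAB_BLANK = "-"


def _taxon_prefix(taxon: int) -> str:
    return "" if taxon == 9606 else f"t{taxon}_"


def generate_ppi_fixture(
    cfg: PpiSimConfig, outdir: str | Path, node_ids: list[str] | None = None
) -> tuple[dict[str, Path], GroundTruth]:
    """Write a small multi-dialect PPI database fixture with ground truth.

    Emits ``ppi_biogrid.tsv``, ``ppi.mitab``, ``orthologs.tsv``,
    ``chaperome.txt``, ``genesets.gmt`` and ``ground_truth.json`` under
    ``outdir``. Edges are assigned to one dialect or to both (so the merge
    step must deduplicate), and each edge carries one taxon; foreign
    identifiers are resolvable through the ortholog table except for IDs
    suppressed with probability ``ortholog_noise``. Passing ``node_ids``
    builds the database over an existing protein namespace (e.g. the IDs of
    a simulated ESC table) instead of fresh ``G####`` symbols.
    """
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    if node_ids is not None:
        if len(node_ids) < cfg.n_nodes:
            raise ConfigError(
                f"invalid config field 'n_nodes': {cfg.n_nodes} nodes requested "
                f"but only {len(node_ids)} IDs supplied"
            )
        nodes = list(node_ids[: cfg.n_nodes])
    else:
        nodes = [f"G{i:04d}" for i in range(cfg.n_nodes)]
    chaperome = set(nodes[: cfg.n_chaperome])

    # undirected edges with layer-dependent probability
    edges: list[tuple[str, str]] = []
    for i in range(cfg.n_nodes):
        for j in range(i + 1, cfg.n_nodes):
            a_core = nodes[i] in chaperome
            b_core = nodes[j] in chaperome
            if a_core and b_core:
                p = cfg.edge_prob_core
            elif a_core or b_core:
                p = cfg.edge_prob_shell
            else:
                p = cfg.edge_prob_outer
            if rng.random() < p:
                edges.append((nodes[i], nodes[j]))

    # per-edge taxon and dialect assignment (human gets double weight so the
    # fixture stays mostly native even with several foreign taxa configured)
    taxa = list(cfg.taxa)
    taxon_probs = np.array([2.0 if t == 9606 else 1.0 for t in taxa])
    taxon_probs = taxon_probs / taxon_probs.sum()
    edge_taxa = [taxa[k] for k in rng.choice(len(taxa), size=len(edges), p=taxon_probs)]
    dialects = [("biogrid", "mitab", "both")[k]
                for k in rng.choice(3, size=len(edges), p=[0.4, 0.4, 0.2])]

    # ortholog table over every foreign identifier that appears
    foreign_ids: dict[tuple[str, int], str] = {}
    for (a, b), taxon in zip(edges, edge_taxa):
        if taxon != 9606:
            for h in (a, b):
                foreign_ids[(f"{_taxon_prefix(taxon)}{h}", taxon)] = h
    suppressed = {
        key for key in sorted(foreign_ids)
        if rng.random() < cfg.ortholog_noise
    }

    # ground truth: the merged human edge set a correct pipeline recovers
    merged: set[tuple[str, str]] = set()
    for (a, b), taxon in zip(edges, edge_taxa):
        if taxon == 9606:
            merged.add((a, b))
        else:
            pre = _taxon_prefix(taxon)
            if (f"{pre}{a}", taxon) not in suppressed and (f"{pre}{b}", taxon) not in suppressed:
                merged.add((a, b))

    biogrid_path = outdir / "ppi_biogrid.tsv"
    mitab_path = outdir / "ppi.mitab"
    ortho_path = outdir / "orthologs.tsv"
    chap_path = outdir / "chaperome.txt"
    gmt_path = outdir / "genesets.gmt"
    truth_path = outdir / "ground_truth.json"

    bg_lines = [
        "#BioGRID Interaction ID\tOfficial Symbol Interactor A\t"
        "Official Symbol Interactor B\tOrganism Interactor A\tOrganism Interactor B"
    ]
    mitab_lines: list[str] = []
    interaction_id = 0
    for (a, b), taxon, dialect in zip(edges, edge_taxa, dialects):
        interaction_id += 1
        pre = _taxon_prefix(taxon)
        ida, idb = f"{pre}{a}", f"{pre}{b}"
        if dialect in ("biogrid", "both"):
            bg_lines.append(f"{interaction_id}\t{ida}\t{idb}\t{taxon}\t{taxon}")
        if dialect in ("mitab", "both"):
            fields = [_MITAB_BLANK] * 15
            fields[0] = f"uniprotkb:{ida}"
            fields[1] = f"uniprotkb:{idb}"
            fields[9] = f"taxid:{taxon}(species {taxon})"
            fields[10] = f"taxid:{taxon}(species {taxon})"
            fields[11] = "psi-mi:\"MI:0915\"(physical association)"
            mitab_lines.append("\t".join(fields))
    biogrid_path.write_text("\n".join(bg_lines) + "\n")
    mitab_path.write_text("\n".join(mitab_lines) + ("\n" if mitab_lines else ""))

    ortho_lines = ["source_id\tsource_taxid\thuman_id"]
    for (sid, taxon), human in sorted(foreign_ids.items()):
        if (sid, taxon) not in suppressed:
            ortho_lines.append(f"{sid}\t{taxon}\t{human}")
    ortho_path.write_text("\n".join(ortho_lines) + "\n")

    chap_path.write_text("".join(f"{g}\n" for g in sorted(chaperome)))

    # gene sets: one planted among chaperome + its direct neighbors, plus
    # decoys drawn uniformly from all nodes
    adjacency: dict[str, set[str]] = {v: set() for v in nodes}
    for a, b in merged:
        adjacency[a].add(b)
        adjacency[b].add(a)
    neighbors_of_core = sorted(
        {v for c in chaperome for v in adjacency[c]} - chaperome
    )
    planted_name = "PLANTED_CHAPEROME_NEIGHBORHOOD"
    n_extra = min(5, len(neighbors_of_core))
    extra = (
        sorted(rng.choice(neighbors_of_core, size=n_extra, replace=False))
        if n_extra else []
    )
    planted = sorted(chaperome) + list(extra)
    gmt_lines = []
    if planted:
        gmt_lines.append(
            "\t".join([planted_name, "planted enriched set"] + list(planted))
        )
    for d in range(cfg.n_decoy_genesets):
        size = int(rng.integers(3, max(4, cfg.n_nodes // 3)))
        size = min(size, cfg.n_nodes) or 1
        members = sorted(rng.choice(nodes, size=size, replace=False))
        gmt_lines.append("\t".join([f"DECOY_{d:02d}", "random decoy set"] + members))
    gmt_path.write_text("\n".join(gmt_lines) + ("\n" if gmt_lines else ""))

    truth = GroundTruth(
        chaperome_ids=chaperome,
        planted_enriched_set=planted_name if planted else None,
        planted_set_members=set(planted),
        merged_human_edges=merged,
        unmapped_source_ids={sid for sid, _ in suppressed},
    )
    truth.to_json(truth_path)

    paths = {
        "biogrid": biogrid_path,
        "mitab": mitab_path,
        "orthologs": ortho_path,
        "chaperome": chap_path,
        "gmt": gmt_path,
        "ground_truth": truth_path,
    }
    return paths, truth
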