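"""One-command two-stage analysis: search, wildcard detection, pruned
re-run, reduced consensus and Bremer supports.

Stage 1 searches the full matrix, takes the strict consensus and ranks
wildcard taxa by positional instability.  The wildcards are excluded from
the matrix and the search re-run (stage 2).  Any taxon still unstable among
the stage-2 trees is pruned a posteriori from the tree set only, and Bremer
supports are reported for the clades of the resulting reduced consensus.
Every number in the report is re-derivable from the emitted trees and the
input matrix, and all randomness flows from the single configured seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .consensus import (ConsensusTree, InstabilityReport, SupportReport,
                        bremer_supports, positional_instability, prune_taxa,
                        strict_consensus, taxon_positions)
from .matrix import CharacterMatrix, ScoringEdit, parse_matrix
from .search import SearchConfig, TreeSet, heuristic_search

__all__ = ["PipelineConfig", "RunReport", "run_paper_pipeline", "write_report"]


@dataclass
class PipelineConfig:
    """Protocol settings; the defaults encode the traditional-search
    protocol (100 random-addition replicates, TBR, hold 10, rule-1
    collapsing)."""

    n_replicates: int = 100
    hold_per_replicate: int = 10
    max_trees: int = 10_000
    seed: int = 0
    outgroup: str | None = None
    dialect: str = "auto"
    merges: list[tuple[str, str]] = field(default_factory=list)
    edits: list[ScoringEdit] = field(default_factory=list)
    ordered_characters: list[int] | None = None   # 1-based override
    exclude: list[str] | str = "auto"
    posterior_prune: list[str] | str = "auto"
    k_max: int = 6
    replication: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None
                  ) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        edits = [ScoringEdit(taxon=e["taxon"], char=int(e["char"]),
                             new=e.get("new"), old=e.get("old"),
                             check_old="old" in e)
                 for e in raw.pop("edits", [])]
        merges = [tuple(m) for m in raw.pop("merges", [])]
        cfg = cls(edits=edits, merges=merges, **raw)
        if seed is not None:
            cfg.seed = seed
        return cfg

    def search_config(self, seed: int) -> SearchConfig:
        return SearchConfig(n_replicates=self.n_replicates,
                            hold_per_replicate=self.hold_per_replicate,
                            max_trees=self.max_trees, seed=seed)


@dataclass
class StageResult:
    matrix: CharacterMatrix
    treeset: TreeSet
    consensus: ConsensusTree
    instability: InstabilityReport | None


@dataclass
class RunReport:
    matrix_digest: str
    config: dict
    stage1: StageResult
    excluded_taxa: list[str]
    stage2: StageResult
    pruned_a_posteriori: list[str]
    pruned_positions: dict[str, int]
    reduced_consensus: ConsensusTree
    bremer: SupportReport

    def as_dict(self) -> dict:
        def stage(s: StageResult) -> dict:
            return {
                "ntax": s.matrix.ntax,
                "nchar": s.matrix.nchar,
                "best_length": s.treeset.length,
                "n_mpts": len(s.treeset),
                "mpts_newick": sorted(t.newick() for t in s.treeset),
                "consensus_newick": s.consensus.newick(),
                "consensus_resolved_clades": s.consensus.n_resolved,
                "instability": (s.instability.as_rows()
                                if s.instability else None),
                "search": {k: v for k, v in s.treeset.provenance.items()
                           if k != "binary_trees"},
            }

        return {
            "matrix_sha256": self.matrix_digest,
            "config": self.config,
            "stage1": stage(self.stage1),
            "excluded_taxa": self.excluded_taxa,
            "stage2": stage(self.stage2),
            "pruned_a_posteriori": self.pruned_a_posteriori,
            "pruned_taxon_positions": self.pruned_positions,
            "reduced_consensus_newick": self.reduced_consensus.newick(),
            "reduced_consensus_resolved_clades":
                self.reduced_consensus.n_resolved,
            "bremer": self.bremer.as_rows(),
        }

    def to_json(self) -> str:
        return json.dumps(self.as_dict(), indent=2, sort_keys=True)

    def to_markdown(self) -> str:
        d = self.as_dict()
        lines = ["# Parsimony analysis report", "",
                 f"Matrix sha256: `{d['matrix_sha256']}`",
                 f"Seed: {d['config'].get('seed')}", ""]
        for name in ("stage1", "stage2"):
            s = d[name]
            lines += [f"## {name}",
                      f"- matrix: {s['ntax']} taxa x {s['nchar']} characters",
                      f"- best length: {s['best_length']} steps",
                      f"- MPTs: {s['n_mpts']}",
                      f"- strict consensus ({s['consensus_resolved_clades']}"
                      f" resolved clades): `{s['consensus_newick']}`", ""]
        lines += [f"Excluded after stage 1: {d['excluded_taxa'] or 'none'}",
                  f"Pruned a posteriori: {d['pruned_a_posteriori'] or 'none'}",
                  f"Reduced consensus: `{d['reduced_consensus_newick']}`", "",
                  "## Bremer supports (reduced consensus clades)", ""]
        for row in d["bremer"]:
            lines.append(f"- {row['clade']}: {row['bremer']}")
        return "\n".join(lines) + "\n"


def run_paper_pipeline(matrix_path: str | Path,
                       config: PipelineConfig | None = None) -> RunReport:
    """Execute the full two-stage protocol on a matrix file."""
    config = config or PipelineConfig()
    text = Path(matrix_path).read_text()
    digest = hashlib.sha256(text.encode()).hexdigest()
    matrix = parse_matrix(text, dialect=config.dialect)

    if config.ordered_characters is not None:
        flags = [False] * matrix.nchar
        for j in config.ordered_characters:
            if not 1 <= j <= matrix.nchar:
                raise ValueError(f"ordered character {j} outside "
                                 f"1..{matrix.nchar}")
            flags[j - 1] = True
        matrix.ordered = flags
    if config.replication and not any(matrix.ordered):
        raise ValueError(
            "replication mode requires an additivity declaration (ccode/"
            "TYPESET in the file or ordered_characters in the config); "
            "refusing to run with every character unordered")

    from .matrix import apply_scoring_edits, merge_otus
    for src, tgt in config.merges:
        matrix = merge_otus(matrix, src, tgt)
    if config.edits:
        matrix = apply_scoring_edits(matrix, config.edits)

    # stage 1: full matrix
    ts1 = heuristic_search(matrix, config.search_config(config.seed))
    cons1 = strict_consensus(ts1)
    pcr1 = positional_instability(ts1)
    excluded = (list(config.exclude) if isinstance(config.exclude, list)
                else list(pcr1.ranking))

    # stage 2: wildcards excluded a priori, search re-run
    if excluded:
        matrix2 = prune_taxa(matrix, excluded, mode="a_priori")
        ts2 = heuristic_search(matrix2, config.search_config(config.seed + 1))
    else:
        matrix2, ts2 = matrix, ts1
    cons2 = strict_consensus(ts2)
    pcr2 = positional_instability(ts2)

    post = (list(config.posterior_prune)
            if isinstance(config.posterior_prune, list)
            else list(pcr2.ranking))
    positions = {lab: taxon_positions(ts2.trees, lab) for lab in post}
    if post:
        reduced = strict_consensus(prune_taxa(ts2, post, mode="a_posteriori"))
    else:
        reduced = cons2
    bremer = bremer_supports(matrix2, ts2, k_max=config.k_max,
                             cap=config.max_trees, prune=post)

    cfg_dict = {k: (v if not isinstance(v, list) or not v or
                    not isinstance(v[0], ScoringEdit)
                    else [vars(e) for e in v])
                for k, v in vars(config).items()}
    return RunReport(
        matrix_digest=digest, config=cfg_dict,
        stage1=StageResult(matrix, ts1, cons1, pcr1),
        excluded_taxa=excluded,
        stage2=StageResult(matrix2, ts2, cons2, pcr2),
        pruned_a_posteriori=post, pruned_positions=positions,
        reduced_consensus=reduced, bremer=bremer)


def write_report(report: RunReport, outdir: str | Path) -> None:
    """Emit trees (Newick), consensus trees, and the JSON/Markdown report."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name, stage in (("stage1", report.stage1), ("stage2", report.stage2)):
        (out / f"{name}_mpts.nwk").write_text(
            "".join(t.newick() + "\n" for t in stage.treeset))
        (out / f"{name}_consensus.nwk").write_text(
            stage.consensus.newick() + "\n")
    (out / "reduced_consensus.nwk").write_text(
        report.reduced_consensus.newick() + "\n")
    (out / "report.json").write_text(report.to_json())
    (out / "report.md").write_text(report.to_markdown())
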