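"""End-to-end pipeline: cohort simulation or file input, CPM normalization,
highly-expressed filtering, differential calling, cross-model signature
derivation, behavior and expression scoring, and score correlation.

In synthetic mode two model cohorts are generated from one seed (emulating
two lupus-prone strains, each with its own control group); the signature is
the hypergeometric-tested intersection of their upregulated genes on the
common highly-expressed background, and scores are computed on the first
cohort. In file mode counts/metadata/behavior are loaded and the signature
is either derived from a single differential comparison or supplied as a
gene list.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as npio
from .expression import CountMatrix, DECriteria, cpm_normalize, differential_genes, filter_highly_expressed
from .scoring import DEFAULT_TESTS, behavior_score, correlate_scores, expression_score
from .signatures import GeneSet, common_background, intersect_signature
from .synthetic import SyntheticConfig, generate_cohort, planted_signature

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "RunReport", "run_pipeline"]

# offset separating the two synthetic model cohorts derived from one seed
_MODEL2_SEED_OFFSET = 10007


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one input route is used: ``synthetic`` (a SyntheticConfig, or
    True for defaults), or file paths for counts/metadata/behavior. The
    signature is derived (default) or read from ``signature_path``.
    """

    synthetic: SyntheticConfig | None = None
    counts_path: str | None = None
    metadata_path: str | None = None
    behavior_path: str | None = None
    signature_path: str | None = None
    filter_threshold: float = 4.0
    max_p: float | None = 0.05
    max_fdr: float | None = None
    min_fold_change: float = 1.5
    case_group: str = "case"
    control_group: str = "control"
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.synthetic is None and self.counts_path is None:
            raise ValueError("either synthetic config or counts_path is required")
        if self.filter_threshold <= 0:
            raise ValueError("filter_threshold must be positive")
        if self.counts_path is not None:
            for name in ("counts_path", "metadata_path", "behavior_path"):
                p = getattr(self, name)
                if p is None:
                    raise ValueError(f"file mode requires {name}")
                if not Path(p).exists():
                    raise FileNotFoundError(f"{name}: no such file {p!r}")
        if self.signature_path is not None and not Path(self.signature_path).exists():
            raise FileNotFoundError(f"signature_path: no such file {self.signature_path!r}")

    def criteria(self) -> DECriteria:
        return DECriteria(
            max_fdr=self.max_fdr, max_p=self.max_p, min_fold_change=self.min_fold_change
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.synthetic is not None:
            d["synthetic"] = dataclasses.asdict(self.synthetic)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("synthetic") is not None:
            d["synthetic"] = SyntheticConfig(**d["synthetic"])
        return cls(**d)


@dataclass
class RunReport:
    """Per-stage record counts and results of one pipeline run."""

    config: dict
    stages: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def add(self, stage: str, **counts) -> None:
        if stage in self.stages:
            raise ValueError(f"stage {stage!r} recorded twice")
        self.stages[stage] = counts

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            raise TypeError(f"not JSON-serializable: {type(o)}")

        return json.dumps(
            {"config": self.config, "stages": self.stages, "warnings": self.warnings},
            indent=2,
            default=default,
        )


def _derive_up_set(
    matrix: CountMatrix, config: PipelineConfig, name: str
) -> tuple[GeneSet, pd.DataFrame, list[str]]:
    expr = cpm_normalize(matrix)
    universe = filter_highly_expressed(expr, matrix.groups, config.filter_threshold)
    de = differential_genes(
        matrix,
        config.case_group,
        config.control_group,
        universe=universe,
        criteria=config.criteria(),
    )
    up = de.index[de["significant"] & (de["direction"] == "up")]
    return GeneSet.from_lists(name, list(up), universe), de, universe


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run the pipeline described by ``config`` and return a RunReport.

    Deterministic given config (including seed). Intermediate artifacts are
    written to ``config.outdir`` when set; a stage failure raises
    PipelineError naming the stage, leaving earlier artifacts plus a
    FAILED marker in place.
    """
    report = RunReport(config=config.to_dict())
    outdir = Path(config.outdir) if config.outdir else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    stage = "input"
    try:
        if config.synthetic is not None:
            syn1 = dataclasses.replace(config.synthetic, seed=int(config.seed))
            syn2 = dataclasses.replace(
                config.synthetic, seed=int(config.seed) + _MODEL2_SEED_OFFSET
            )
            battery, counts1, severity = generate_cohort(syn1)
            _, counts2, _ = generate_cohort(syn2)
            planted = planted_signature(syn1)
            report.add(
                "input",
                mode="synthetic",
                animals=len(battery),
                genes=counts1.counts.shape[0],
                planted_signature_size=len(planted),
            )
            if outdir is not None:
                npio.write_behavior(battery, outdir / "behavior.csv")
                npio.write_counts(counts1, outdir / "counts_model1.tsv")
                npio.write_counts(counts2, outdir / "counts_model2.tsv")
                severity.to_csv(outdir / "severity.csv", index_label="animal_id")
                npio.write_config(config.to_dict(), outdir / "config.yaml")
        else:
            counts1 = npio.read_counts(config.counts_path, config.metadata_path)
            battery = npio.read_behavior(config.behavior_path)
            counts2 = None
            report.add(
                "input",
                mode="files",
                animals=len(battery),
                genes=counts1.counts.shape[0],
            )

        stage = "signature"
        if config.signature_path is not None:
            genes = npio.read_gene_list(config.signature_path)
            signature = GeneSet.from_lists("supplied", genes, counts1.gene_ids)
            report.add("signature", source="supplied", size=len(signature))
        elif counts2 is not None:
            up1, de1, universe1 = _derive_up_set(counts1, config, "model1_up")
            up2, de2, universe2 = _derive_up_set(counts2, config, "model2_up")
            background = common_background(universe1, universe2)
            signature, overlap = intersect_signature(up1, up2)
            report.add(
                "signature",
                source="derived",
                universe_model1=len(universe1),
                universe_model2=len(universe2),
                common_background=overlap.N,
                up_model1=overlap.K,
                up_model2=overlap.n,
                size=overlap.k,
                expected_overlap=overlap.expected,
                enrichment=overlap.enrichment,
                p_over=overlap.p_over,
            )
            if outdir is not None:
                de1.to_csv(outdir / "de_model1.csv", index_label="gene")
                de2.to_csv(outdir / "de_model2.csv", index_label="gene")
                npio.write_gene_list(signature.member_names(), outdir / "signature.txt")
        else:
            up1, de1, universe1 = _derive_up_set(counts1, config, "up")
            signature = up1
            report.add(
                "signature",
                source="derived_single_model",
                universe=len(universe1),
                size=len(signature),
            )
            if outdir is not None:
                de1.to_csv(outdir / "de.csv", index_label="gene")
                npio.write_gene_list(signature.member_names(), outdir / "signature.txt")

        stage = "scoring"
        subtests = battery.drop(columns=["group"], errors="ignore")
        b_scores = behavior_score(subtests, DEFAULT_TESTS)
        e_scores = expression_score(cpm_normalize(counts1), signature)
        report.add(
            "scoring",
            animals_scored=int(b_scores.notna().sum()),
            signature_genes_used=e_scores.genes_used,
            signature_genes_dropped=e_scores.genes_dropped,
        )

        stage = "correlation"
        corr = correlate_scores(e_scores.scores, b_scores)
        report.add("correlation", r=corr.r, n=corr.n, p=corr.p)
        if outdir is not None:
            pd.DataFrame(
                {"behavior_score": b_scores, "expression_score": e_scores.scores}
            ).to_csv(outdir / "scores.csv", index_label="animal_id")
            (outdir / "run_report.json").write_text(report.to_json())
    except Exception as exc:  # noqa: BLE001 - stage name is part of the contract
        if outdir is not None:
            (outdir / "FAILED").write_text(f"stage: {stage}\ncause: {exc}\n")
        raise PipelineError(stage, exc) from exc
    return report
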