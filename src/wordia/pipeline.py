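"""End-to-end pipeline: simulate -> preprocess -> ia -> analyze -> report.

A single YAML config drives every stage, so different stimulus conditions
are configuration rather than code.  Each stage reads/writes the plain-text
tables defined in :mod:`wordia.io_model`; a manifest of SHA-256 hashes makes
end-to-end determinism checkable (same config + seed -> same hashes).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io_model, preprocessing, synthetic
from .ia import build_response_matrices, compute_all_ia
from .io_model import ValidationError
from .stats import (
    anova_oneway,
    attach_zipf,
    category_proportions,
    confidence_per_word_image,
    pearson_with_bf,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; unknown keys are rejected on load."""

    out_dir: str = "wordia_out"
    seed: int = 0
    simulate: bool = True
    simulation: dict = field(default_factory=dict)  # SimulationConfig overrides
    responses_path: str | None = None  # used when simulate is False
    frequency_path: str | None = None
    categories_path: str | None = None
    auto_accept_corrections: bool = True
    row_matching: str = "index"
    condition_tag: str = "intact"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self)), encoding="utf-8")
        return path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and return the artifact manifest.

    On a stage failure the exception propagates after a ``<stage>.failed``
    marker is written, so partial outputs remain inspectable.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    stage = "setup"
    try:
        # ---- simulate or load ------------------------------------------------
        stage = "simulate"
        if cfg.simulate:
            sim_cfg = synthetic.SimulationConfig(
                seed=cfg.seed, condition_tag=cfg.condition_tag, **cfg.simulation
            )
            exp, truth, freq = synthetic.simulate_experiment(sim_cfg)
            labels = truth.label_set()
            artifacts["responses"] = str(io_model.write_responses(exp, out / "responses.csv"))
            artifacts["frequency"] = str(io_model.write_frequency_table(freq, out / "frequency.tsv"))
            artifacts["categories"] = str(io_model.write_categories(labels, out / "categories.csv"))
            truth.token_categories.to_csv(out / "ground_truth.csv", index=False)
            artifacts["ground_truth"] = str(out / "ground_truth.csv")
        else:
            if not cfg.responses_path or not Path(cfg.responses_path).exists():
                raise ValidationError(f"missing input: responses file {cfg.responses_path!r}")
            if not cfg.frequency_path or not Path(cfg.frequency_path).exists():
                raise ValidationError(f"missing input: frequency table {cfg.frequency_path!r}")
            exp = io_model.read_responses(cfg.responses_path, condition_tag=cfg.condition_tag)
            freq = io_model.read_frequency_table(cfg.frequency_path)
            labels = (
                io_model.read_categories(cfg.categories_path)
                if cfg.categories_path
                else None
            )

        # ---- preprocess ------------------------------------------------------
        stage = "preprocess"
        result = preprocessing.preprocess(
            exp,
            spell_provider=preprocessing.FrequencySpellChecker(freq),
            lemma_provider=preprocessing.RuleLemmatizer(freq.words()),
            auto_accept=freq if cfg.auto_accept_corrections else None,
        )
        result.frame.to_csv(out / "processed.csv", index=False)
        artifacts["processed"] = str(out / "processed.csv")
        preprocessing.write_ledger(result.corrections, out / "corrections.csv")
        preprocessing.write_ledger(result.lemmas, out / "lemmas.csv")
        (out / "drop_report.json").write_text(json.dumps(result.drop_counts, indent=2))

        # ---- IA --------------------------------------------------------------
        stage = "ia"
        matrices = build_response_matrices(result.frame)
        scores = compute_all_ia(matrices, row_matching=cfg.row_matching)
        scores.to_csv(out / "ia_scores.csv", index=False)
        artifacts["ia_scores"] = str(out / "ia_scores.csv")

        # ---- analyze ---------------------------------------------------------
        stage = "analyze"
        report_lines = [
            "# wordia analysis report", "",
            f"Images scored: {scores['image_id'].nunique()}",
            f"Scorable word-image pairs: {len(scores)}",
            f"Mean word IA: {scores['ia'].mean():.4f} (SD {scores['ia'].std():.4f})", "",
        ]
        corr_rows = []
        with_zipf = attach_zipf(scores, freq)
        c = pearson_with_bf(with_zipf["ia"], with_zipf["zipf"])
        corr_rows.append(("ia_vs_zipf", c.r, c.n, c.p_two_sided, c.bf10, *c.ci95))
        report_lines.append(
            f"IA vs Zipf frequency: r({c.n - 2}) = {c.r:.3f}, p = {c.p_two_sided:.3g}, "
            f"BF10 = {c.bf10:.3g}"
        )
        conf = confidence_per_word_image(matrices, scores)
        joined = scores.merge(conf, on=["word", "image_id"])
        c2 = pearson_with_bf(joined["ia"], joined["mean_confidence"])
        corr_rows.append(("ia_vs_confidence", c2.r, c2.n, c2.p_two_sided, c2.bf10, *c2.ci95))
        report_lines.append(
            f"IA vs mean confidence: r({c2.n - 2}) = {c2.r:.3f}, p = {c2.p_two_sided:.3g}, "
            f"BF10 = {c2.bf10:.3g}"
        )
        pd.DataFrame(
            corr_rows, columns=["analysis", "r", "n", "p", "bf10", "ci_low", "ci_high"]
        ).to_csv(out / "correlations.csv", index=False)
        artifacts["correlations"] = str(out / "correlations.csv")

        if labels is not None:
            props = category_proportions(scores, labels)
            props.per_image.to_csv(out / "proportions.csv", index=False)
            artifacts["proportions"] = str(out / "proportions.csv")
            report_lines.append("")
            report_lines.append("Mean per-image category proportions:")
            for cat, val in props.summary.items():
                report_lines.append(f"  {cat}: {val:.3f}")
            labeled = joined.assign(
                category=[
                    labels.get(w, i) for w, i in zip(joined["word"], joined["image_id"])
                ]
            )
            counts = labeled["category"].value_counts()
            usable = [c_ for c_ in counts.index if counts[c_] >= 2]
            if len(usable) >= 2:
                sub = labeled[labeled["category"].isin(usable)]
                an = anova_oneway(sub["mean_confidence"], sub["category"])
                an_df = pd.DataFrame(
                    [(an.f, an.df_between, an.df_within, an.p, an.bf10_approx)],
                    columns=["f", "df_between", "df_within", "p", "bf10_approx"],
                )
                an_df.to_csv(out / "anova.csv", index=False)
                artifacts["anova"] = str(out / "anova.csv")
                report_lines.append("")
                report_lines.append(
                    f"Confidence by category: F({an.df_between}, {an.df_within}) = "
                    f"{an.f:.2f}, p = {an.p:.3g}, BF10 (BIC approx.) = {an.bf10_approx:.3g}"
                )
                for g_, m_ in an.group_means.items():
                    report_lines.append(f"  {g_}: mean confidence {m_:.3f}")

        stage = "report"
        (out / "report.md").write_text("\n".join(report_lines) + "\n", encoding="utf-8")
        artifacts["report"] = str(out / "report.md")
    except Exception:
        (out / f"{stage}.failed").touch()
        raise

    manifest = {
        name: {"path": path, "sha256": _sha256(Path(path))}
        for name, path in artifacts.items()
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    return manifest
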