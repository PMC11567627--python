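"""Executable architecture ablations: the five component variants.

Each variant toggles one axis of the architecture — embedding kind (linear
patch + positional encoding vs convolutional), downsampling kind (patch
merging vs strided convolution), local/global transformer depths, and skip
attention — so the contribution of every component can be measured under
an identical training budget and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import pandas as pd

from .model import EDTNet, ModelConfig, build_edtnet, count_parameters
from .pipeline import RunConfig, evaluate_model, train
from .phantoms import load_dataset, split_dataset

__all__ = ["AblationVariant", "TABLE_VARIANTS", "variant_by_label",
           "build_variant", "run_ablation"]


@dataclass(frozen=True)
class AblationVariant:
    label: str
    esla_depth: int
    esga_depth: int
    downsample_kind: str       # "patch_merge" | "conv"
    embedding_kind: str        # "linear_patch" | "conv"
    skip_attention: bool

    def apply(self, base: ModelConfig) -> ModelConfig:
        return replace(base, esla_depth=self.esla_depth,
                       esga_depth=self.esga_depth,
                       downsample_kind=self.downsample_kind,
                       embedding_kind=self.embedding_kind,
                       skip_attention=self.skip_attention)


#: The five component combinations of the ablation matrix, in increasing
#: order of architectural completeness; the last row is the full model.
TABLE_VARIANTS: tuple[AblationVariant, ...] = (
    AblationVariant("1xESLA-MSA+PM+PE", 1, 0, "patch_merge", "linear_patch", False),
    AblationVariant("1xESLA-MSA+PM+Conv_embedding", 1, 0, "patch_merge", "conv", False),
    AblationVariant("1xESLA-MSA+Conv_downsampling+Conv_embedding",
                    1, 0, "conv", "conv", False),
    AblationVariant("1xESLA-MSA+1xESGA-MSA+Conv_downsampling+Conv_embedding",
                    1, 1, "conv", "conv", False),
    AblationVariant("2xESLA-MSA+2xESGA-MSA+Conv_downsampling+Conv_embedding"
                    "+Skip Attention", 2, 2, "conv", "conv", True),
)


def variant_by_label(label: str) -> AblationVariant:
    for v in TABLE_VARIANTS:
        if v.label == label:
            return v
    raise KeyError(f"unknown ablation variant {label!r}; known labels: "
                   f"{[v.label for v in TABLE_VARIANTS]}")


def build_variant(variant: AblationVariant, base: ModelConfig) -> EDTNet:
    """Build the network for one variant on top of a base configuration."""
    return build_edtnet(variant.apply(base))


def run_ablation(variants: Sequence[AblationVariant], data_dir: str | Path,
                 run: RunConfig, out_dir: str | Path) -> pd.DataFrame:
    """Train every variant under the identical RunConfig and tabulate metrics.

    All variants are built up front, so a misconfigured variant aborts the
    run before any training starts. Each variant trains from the same seed
    on the same split; the table reports validation mean IoU and DSC.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    configs = [variant.apply(run.model) for variant in variants]
    models = {}
    for variant, cfg in zip(variants, configs):
        models[variant.label] = build_edtnet(cfg)  # fail fast, full matrix

    samples = load_dataset(data_dir)
    rows = []
    for variant, cfg in zip(variants, configs):
        variant_run = replace(run, model=cfg)
        vdir = out_dir / _slug(variant.label)
        result = train(variant_run, data_dir, vdir)
        _, val_set = split_dataset(samples, run.train_fraction,
                                   seed=run.seed, leak_free=run.leak_free)
        eval_set = val_set if val_set else samples
        metrics = evaluate_model(result.model, eval_set, run.threshold)
        rows.append({"label": variant.label,
                     "params": count_parameters(result.model),
                     "mean_iou": metrics["mean"]["iou"],
                     "mean_dsc": metrics["mean"]["dsc"]})
    frame = pd.DataFrame(rows, columns=["label", "params", "mean_iou", "mean_dsc"])
    frame.to_csv(out_dir / "ablation.csv", index=False)
    return frame


def _slug(label: str) -> str:
    return "".join(c if c.isalnum() else "_" for c in label).strip("_")
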