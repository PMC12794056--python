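"""End-to-end automated fibrosis mapping (AFM) runs.

One run takes, per disease group, one or more (image, annotation) slide
pairs, extracts a fixed-size tile around every annotated tubule, segments
fibrosis by the HSV threshold, and compares distal vs proximal tile metrics
within each group. Tiles from a group's slides are pooled into a single
test, and a per-slide breakdown is emitted alongside so slide-level
clustering stays visible; no mixed model is fitted.

Outputs: a per-tile CSV (fixed schema, so the statistics stage can be re-run
without re-segmentation), a summary table with one row per disease group
(per-class n, mean metric in percent, t and U p-values), and a JSON manifest
recording every parameter, input checksum, and the package version — the
original green threshold was chosen by eye, so full auditability of the
threshold actually used stands in for it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .annotations import read_annotations
from .errors import ConfigError, InsufficientGroupsError
from .imaging import FibrosisParams, load_image
from .metrics import TILE_CSV_COLUMNS, compute_tile_metrics, records_to_frame
from .stats import DEFAULT_EXACT_CUTOFF, GroupComparisonResult, compare_groups

logger = logging.getLogger(__name__)

SUMMARY_COLUMNS = [
    "disease",
    "n_distal",
    "fibrotic_metric_distal",
    "n_proximal",
    "fibrotic_metric_proximal",
    "p_t",
    "p_u",
]


@dataclass
class SlidePair:
    image_path: str
    annotation_path: str
    slide_id: str = ""

    def __post_init__(self) -> None:
        if not self.slide_id:
            self.slide_id = Path(self.image_path).stem


@dataclass
class RunConfig:
    """Everything a reproducible AFM run depends on."""

    groups: dict[str, list[SlidePair]]  # disease -> slide pairs
    nominal_size: int = 512
    params: FibrosisParams = field(default_factory=FibrosisParams)
    edge_policy: str = "clip"
    exclude_tubule_interior: bool = False
    t_flavor: str = "welch"
    alternative: str = "two-sided"
    exact_cutoff: int = DEFAULT_EXACT_CUTOFF
    strict: bool = False
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.nominal_size < 64 or self.nominal_size % 2:
            raise ConfigError(f"nominal_size must be even and >= 64, got {self.nominal_size}")
        if not self.groups:
            raise ConfigError("no slides configured")


def _sha256(path: str) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def run_afm(
    config: RunConfig,
) -> tuple[pd.DataFrame, dict[str, GroupComparisonResult], dict]:
    """Run the full AFM analysis; returns (per-tile table, per-group results, manifest).

    The per-tile table's ``slide_id`` is ``"<disease>:<slide>"`` so the
    group assignment survives a stats-only rerun from the CSV alone.
    """
    frames = []
    checksums = {}
    for disease, pairs in config.groups.items():
        for pair in pairs:
            image = load_image(pair.image_path)
            annotations = read_annotations(pair.annotation_path, strict=config.strict)
            records = compute_tile_metrics(
                image,
                annotations,
                config.params,
                nominal_size=config.nominal_size,
                edge_policy=config.edge_policy,
                exclude_tubule_interior=config.exclude_tubule_interior,
                slide_id=f"{disease}:{pair.slide_id}",
                strict=config.strict,
            )
            frames.append(records_to_frame(records))
            checksums[pair.image_path] = _sha256(pair.image_path)
            checksums[pair.annotation_path] = _sha256(pair.annotation_path)
    tile_frame = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=TILE_CSV_COLUMNS)
    )
    results = group_results(tile_frame, config)
    manifest = {
        "afm_version": __version__,
        "parameters": {
            "nominal_size": config.nominal_size,
            "fibrosis_params": config.params.as_dict(),
            "edge_policy": config.edge_policy,
            "exclude_tubule_interior": config.exclude_tubule_interior,
            "t_flavor": config.t_flavor,
            "alternative": config.alternative,
            "exact_cutoff": config.exact_cutoff,
        },
        "inputs_sha256": checksums,
        "n_tiles": int(len(tile_frame)),
    }
    if config.out_dir is not None:
        write_outputs(tile_frame, results, manifest, config.out_dir)
    return tile_frame, results, manifest


def group_results(
    tile_frame: pd.DataFrame, config: RunConfig
) -> dict[str, GroupComparisonResult]:
    """Pooled distal-vs-proximal comparison for each disease group."""
    results: dict[str, GroupComparisonResult] = {}
    diseases = tile_frame["slide_id"].str.split(":").str[0]
    for disease in dict.fromkeys(diseases):  # preserve first-seen order
        sub = tile_frame[diseases == disease]
        try:
            results[disease] = compare_groups(
                sub,
                alternative=config.alternative,
                t_flavor=config.t_flavor,
                exact_cutoff=config.exact_cutoff,
            )
        except InsufficientGroupsError:
            if config.strict:
                raise
            logger.warning("group %s: fewer than 2 tiles in a class; skipped", disease)
    return results


def summary_frame(results: dict[str, GroupComparisonResult]) -> pd.DataFrame:
    rows = [
        {
            "disease": disease,
            "n_distal": r.n_distal,
            "fibrotic_metric_distal": r.mean_distal,
            "n_proximal": r.n_proximal,
            "fibrotic_metric_proximal": r.mean_proximal,
            "p_t": r.p_t,
            "p_u": r.p_u,
        }
        for disease, r in results.items()
    ]
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def format_summary(results: dict[str, GroupComparisonResult]) -> str:
    """Human-readable summary mirroring the one-row-per-disease table layout."""
    frame = summary_frame(results)
    lines = [
        f"{'Disease':<28}{'n dist':>8}{'metric':>8}{'n prox':>8}"
        f"{'metric':>8}{'p (t)':>10}{'p (U)':>10}"
    ]
    for _, row in frame.iterrows():
        lines.append(
            f"{row['disease']:<28}{row['n_distal']:>8d}"
            f"{row['fibrotic_metric_distal']:>8.1f}{row['n_proximal']:>8d}"
            f"{row['fibrotic_metric_proximal']:>8.1f}"
            f"{row['p_t']:>10.3g}{row['p_u']:>10.3g}"
        )
    return "\n".join(lines)


def write_outputs(
    tile_frame: pd.DataFrame,
    results: dict[str, GroupComparisonResult],
    manifest: dict,
    out_dir,
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tile_frame.to_csv(out / "tiles.csv", index=False)
    summary_frame(results).to_csv(out / "summary.csv", index=False)
    (out / "summary.txt").write_text(format_summary(results) + "\n")
    per_slide = (
        tile_frame.groupby(["slide_id", "tubule_class"])["fibrotic_fraction"]
        .agg(["count", "mean", "median"])
        .reset_index()
    )
    per_slide.to_csv(out / "per_slide.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def stats_from_csv(
    path,
    *,
    alternative: str = "two-sided",
    t_flavor: str = "welch",
    exact_cutoff: int = DEFAULT_EXACT_CUTOFF,
    strict: bool = False,
):
    """Re-run only the statistics stage from a previously written per-tile CSV."""
    frame = pd.read_csv(
        path,
        dtype={"slide_id": str, "tubule_id": str},
        float_precision="round_trip",  # bit-exact reload of the written metrics
    )
    cfg = RunConfig.__new__(RunConfig)  # stats-only: no slide inputs to validate
    cfg.alternative, cfg.t_flavor = alternative, t_flavor
    cfg.exact_cutoff, cfg.strict = exact_cutoff, strict
    return frame, group_results(frame, cfg)
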