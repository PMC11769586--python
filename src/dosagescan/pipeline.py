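"""End-to-end pipeline driven by a run manifest.

The manifest (JSON) names the registry, the exclusion mask, the synteny
map and the per-sample depth tables with their pedigree roles, plus the
windowing/calling parameters.  :func:`run_pipeline` chains windowing →
scoring → segmentation → event pairing → provenance → native typing and
writes every stage's output under one directory.  Outputs are pure
functions of the manifest and its inputs, so a rerun reproduces them
byte-for-byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import coverage, dosage, hrcall, maskfilters, simulate
from .refbuild import load_registry

__all__ = ["RunManifest", "ManifestError", "StageError", "run_pipeline"]

log = logging.getLogger("dosagescan")

ROLES = ("diploid_parent", "allotetraploid_parent", "F1", "BC1F1", "BC2F1")

#: scoring mode per pedigree role: the allotetraploid is normalized per
#: subgenome; everything sitting on a disomic A background uses the
#: A-genome median genome-wide.
ROLE_MODE = {
    "diploid_parent": "backcross",
    "allotetraploid_parent": "allotetraploid",
    "F1": "backcross",
    "BC1F1": "backcross",
    "BC2F1": "backcross",
}


class ManifestError(ValueError):
    """Invalid or incomplete run manifest (exit code 2)."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name (exit code 3)."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunManifest:
    registry: Path
    synteny: Path
    samples: list[dict]  # {"id", "role", "depth"}
    mask: Path | None = None
    window: int = 2_000_000
    step: int = 500_000
    exclusion_fraction: float = 0.95
    shift_threshold: float = 0.5
    neighborhood: int = 2_000_000
    min_shared: int = 2
    seed: int = 0
    params: dict = field(default_factory=dict)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunManifest":
        path = Path(path)
        try:
            raw = json.loads(path.read_text())
        except (OSError, json.JSONDecodeError) as exc:
            raise ManifestError(f"cannot read manifest {path}: {exc}") from exc
        base = path.parent

        def resolve(p: str) -> Path:
            q = Path(p)
            return q if q.is_absolute() else base / q

        try:
            m = cls(
                registry=resolve(raw["registry"]),
                synteny=resolve(raw["synteny"]),
                samples=raw["samples"],
                mask=resolve(raw["mask"]) if raw.get("mask") else None,
                **{
                    k: raw[k]
                    for k in (
                        "window", "step", "exclusion_fraction", "shift_threshold",
                        "neighborhood", "min_shared", "seed",
                    )
                    if k in raw
                },
            )
        except KeyError as exc:
            raise ManifestError(f"manifest missing required field {exc}") from exc
        for s in m.samples:
            for key in ("id", "role", "depth"):
                if key not in s:
                    raise ManifestError(f"sample entry missing {key!r}: {s}")
            if s["role"] not in ROLES:
                raise ManifestError(f"unknown sample role {s['role']!r} for {s['id']}")
            s["depth"] = str(resolve(s["depth"]))
        for p in [m.registry, m.synteny, m.mask, *[s["depth"] for s in m.samples]]:
            if p is not None and not Path(p).exists():
                raise ManifestError(f"manifest references missing file: {p}")
        return m


def run_pipeline(manifest: RunManifest, out_dir: str | Path) -> Path:
    """Run windowing → scoring → HR calling for every manifest sample.

    Writes per-sample scored window tables and segmentations, plus a
    cross-individual event report (``events.tsv`` / ``events.json``).
    Backcross-generation samples drive event calling; the allotetraploid
    parent, when present, types the common events (reciprocal vs
    nonreciprocal) and typed common events are marked native.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log.info("loading registry and annotations")
    try:
        registry = load_registry(manifest.registry)
        synteny = simulate.read_synteny_tsv(manifest.synteny)
        mask = (
            maskfilters.AnalysisMask.from_bed(manifest.mask, registry.lengths)
            if manifest.mask
            else None
        )
    except Exception as exc:
        raise StageError("load-inputs", str(exc)) from exc

    scored: dict[str, "object"] = {}
    roles: dict[str, str] = {}
    for s in manifest.samples:
        sid, role = s["id"], s["role"]
        roles[sid] = role
        log.info("sample %s (%s): depth -> windows -> score", sid, role)
        try:
            track = coverage.depth_from_table(s["depth"], registry)
            table = coverage.window_means(
                track,
                mask,
                window=manifest.window,
                step=manifest.step,
                exclusion_fraction=manifest.exclusion_fraction,
            )
            ctx = dosage.compute_M(table, registry, ROLE_MODE[role])
            table = dosage.score(table, ctx)
        except Exception as exc:
            raise StageError(f"score:{sid}", str(exc)) from exc
        scored[sid] = table
        coverage.write_window_table(table, out / f"{sid}.windows.tsv")

    events_by_indiv: dict[str, list[hrcall.HREvent]] = {}
    for sid, table in scored.items():
        if roles[sid] not in ("BC1F1", "BC2F1", "F1"):
            continue
        try:
            segs = hrcall.segment_scores(table, shift_threshold=manifest.shift_threshold)
            hrcall.write_segments_tsv(segs, out / f"{sid}.segments.tsv")
            events_by_indiv[sid] = hrcall.pair_events(
                segs, registry, synteny, neighborhood=manifest.neighborhood,
                boundary_halfwidth=manifest.step,
            )
        except Exception as exc:
            raise StageError(f"call-hr:{sid}", str(exc)) from exc

    try:
        events = hrcall.classify_provenance(
            events_by_indiv,
            min_shared=manifest.min_shared,
            neighborhood=manifest.neighborhood,
        )
    except Exception as exc:
        raise StageError("classify", str(exc)) from exc

    parent_id = next(
        (sid for sid, r in roles.items() if r == "allotetraploid_parent"), None
    )
    if parent_id is not None:
        for ev in events:
            if ev.provenance == "common" and ev.a_site and ev.c_site:
                ev.type = hrcall.classify_native_type(
                    scored[parent_id], ev, span=manifest.window
                )
                if ev.type != "unknown":
                    ev.provenance = "native"

    events.sort(
        key=lambda e: (
            e.a_site.chrom if e.a_site else "~",
            e.a_site.start if e.a_site else -1,
            e.c_site.chrom if e.c_site else "~",
        )
    )
    hrcall.write_events_tsv(events, out / "events.tsv")
    hrcall.write_events_json(events, out / "events.json")
    log.info("wrote %d events to %s", len(events), out / "events.tsv")
    return out
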