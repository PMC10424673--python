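"""End-to-end design pipeline: configuration, orchestration, manifests.

One YAML file describes a run: the scaffold and its segmentation into
overlapping helices with their hotspots, the atom-level scheme, the
library to mirror and scan, search settings, and the splice plan. The
pipeline itself is fully deterministic — identical inputs produce
byte-identical outputs — and every stage logs one structured line with
its counts. Outputs are individually reloadable (TSV/PDB/JSON) and a
manifest records their SHA-256 checksums.
"""
from __future__ import annotations

import dataclasses
import glob
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import assembly as asm
from . import fragment_search as fs
from . import query_builder as qb
from . import structure_io as sio
from .errors import ConfigError, PipelineStageError

__all__ = ["SegmentConfig", "PipelineConfig", "load_config", "run_design"]

logger = logging.getLogger(__name__)


@dataclass
class SegmentConfig:
    helix_id: str
    start: int
    end: int
    hotspots: list[qb.HotspotSpec]


@dataclass
class PipelineConfig:
    scaffold_path: str
    chain_id: str
    segments: list[SegmentConfig]
    library_paths: list[str]  # files or directories of PDB/mmCIF files
    out_dir: str
    scheme: qb.AtomLevelScheme = field(default_factory=qb.default_scheme)
    top_k: int = 1000
    directions: tuple[str, ...] = ("forward", "reverse")
    identity_filter: bool = False
    require_helix: bool = False
    plan: asm.SplicePlan | None = None  # None -> midpoint default
    d_naming: str = "plain"
    seed: int = 0

    def validate(self) -> None:
        if not os.path.exists(self.scaffold_path):
            raise ConfigError(f"scaffold file not found: {self.scaffold_path}")
        if not self.segments:
            raise ConfigError("no segments configured")
        for p in self.library_paths:
            if not os.path.exists(p):
                raise ConfigError(f"library path not found: {p}")
        if not self.library_paths:
            raise ConfigError("no library paths configured")
        if self.top_k < 1:
            raise ConfigError(f"top_k must be >= 1, got {self.top_k}")
        for d in self.directions:
            if d not in fs.DIRECTIONS:
                raise ConfigError(f"unknown direction {d!r}")


def _parse_hotspot(entry: dict) -> qb.HotspotSpec:
    try:
        res_name = str(entry["res_name"]).upper()
        if len(res_name) == 1:
            res_name = qb.ONE_TO_THREE[res_name]
        return qb.HotspotSpec(
            seq_id=int(entry["seq_id"]), res_name=res_name, rationale=str(entry.get("rationale", ""))
        )
    except KeyError as exc:
        raise ConfigError(f"hotspot entry {entry!r} missing key {exc}") from exc


def load_config(path: str) -> PipelineConfig:
    """Parse and validate a pipeline YAML file (see docs for the layout)."""
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")

    base = os.path.dirname(os.path.abspath(path))

    def _resolve(p: str) -> str:
        return p if os.path.isabs(p) else os.path.join(base, p)

    try:
        segments = []
        for helix_id, seg in raw["segments"].items():
            segments.append(
                SegmentConfig(
                    helix_id=str(helix_id),
                    start=int(seg["start"]),
                    end=int(seg["end"]),
                    hotspots=[_parse_hotspot(h) for h in seg.get("hotspots", [])],
                )
            )
        scheme = qb.default_scheme()
        if isinstance(raw.get("scheme"), dict):
            scheme = qb.AtomLevelScheme(
                overrides={
                    res: [tuple(level) for level in levels]
                    for res, levels in raw["scheme"].items()
                }
            )
        directions = raw.get("directions", "both")
        if directions == "both":
            directions = ("forward", "reverse")
        elif isinstance(directions, str):
            directions = (directions,)
        else:
            directions = tuple(directions)
        plan = None
        if isinstance(raw.get("plan"), list):
            plan = asm.SplicePlan(
                tuple((str(c["helix_id"]), int(c["start"]), int(c["end"])) for c in raw["plan"])
            )
        library = raw["library"]
        if isinstance(library, str):
            library = [library]
        cfg = PipelineConfig(
            scaffold_path=_resolve(str(raw["scaffold"])),
            chain_id=str(raw.get("chain", "A")),
            segments=segments,
            library_paths=[_resolve(str(p)) for p in library],
            out_dir=_resolve(str(raw["out_dir"])),
            scheme=scheme,
            top_k=int(raw.get("top_k", 1000)),
            directions=directions,
            identity_filter=bool(raw.get("identity_filter", False)),
            require_helix=bool(raw.get("require_helix", False)),
            plan=plan,
            d_naming=str(raw.get("d_naming", "plain")),
            seed=int(raw.get("seed", 0)),
        )
    except KeyError as exc:
        raise ConfigError(f"{path}: missing required key {exc}") from exc
    cfg.validate()
    return cfg


def _load_library_structures(paths: list[str]) -> list[sio.StructureModel]:
    files: list[str] = []
    for p in paths:
        if os.path.isdir(p):
            for pattern in ("*.pdb", "*.ent", "*.cif"):
                files.extend(sorted(glob.glob(os.path.join(p, pattern))))
        else:
            files.append(p)
    if not files:
        raise ConfigError(f"no structure files found under {paths}")
    return [sio.read_structure(f) for f in files]


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _matches_frame(profiles: dict[str, fs.RMSDProfile]) -> pd.DataFrame:
    rows = []
    for helix_id, profile in profiles.items():
        for rank, m in enumerate(profile.matches, start=1):
            rows.append(
                {
                    "helix_id": helix_id,
                    "rank": rank,
                    "entry_id": m.window.entry_id,
                    "chain_id": m.window.chain_id,
                    "start": m.window.start,
                    "direction": m.window.direction,
                    "combo_id": "-".join(map(str, m.combo_id)),
                    "rmsd": round(m.rmsd, 6),
                    "matched_residues": "-".join(m.matched_residues),
                }
            )
    return pd.DataFrame(rows)


def rescore_match(
    row: dict,
    queries_by_helix: dict[str, list[qb.QueryStructure]],
    library: fs.FragmentLibrary,
) -> fs.FragmentMatch:
    """Rebuild a FragmentMatch from one matches.tsv row by re-scoring the
    named window with the named query combination (deterministic, so the
    stored RMSD is reproduced exactly)."""
    helix_id = str(row["helix_id"])
    combo = tuple(int(x) for x in str(row["combo_id"]).split("-"))
    candidates = [q for q in queries_by_helix[helix_id] if q.combo_id == combo]
    if not candidates:
        raise ConfigError(f"matches row references unknown combo {row['combo_id']} for {helix_id}")
    query = candidates[0]
    window = fs.FragmentWindow(
        entry_id=str(row["entry_id"]),
        chain_id=str(row["chain_id"]),
        start=int(row["start"]),
        length=query.span_length,
        direction=str(row["direction"]),
    )
    match = fs.score_window(query, window, library)
    if match is None:
        raise ConfigError(f"window {window} is no longer scoreable against {helix_id}")
    return match


def run_design(config: PipelineConfig):
    """Execute build-queries -> build-library -> search -> assemble and
    write the output bundle (tables, PDB, geometry report, manifest)."""
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    stage = "read_scaffold"
    outputs: dict[str, str] = {}
    counts: dict[str, dict] = {}
    try:
        scaffold = sio.read_structure(config.scaffold_path)

        stage = "build_queries"
        segments: dict[str, sio.Segment] = {}
        queries: dict[str, list[qb.QueryStructure]] = {}
        query_rows = []
        for seg_cfg in config.segments:
            segment = sio.extract_segment(scaffold, config.chain_id, seg_cfg.start, seg_cfg.end)
            hotspots = qb.define_hotspots(segment, seg_cfg.hotspots)
            qs = qb.enumerate_queries(hotspots, config.scheme, helix_id=seg_cfg.helix_id)
            segments[seg_cfg.helix_id] = segment
            queries[seg_cfg.helix_id] = qs
            for q in qs:
                query_rows.append(
                    {
                        "helix_id": q.helix_id,
                        "combo_id": "-".join(map(str, q.combo_id)),
                        "n_atoms": len(q.atoms),
                        "atoms": ";".join(f"{s}:{n}" for s, n in q.atoms),
                    }
                )
            logger.info("queries %s: %d combinations", seg_cfg.helix_id, len(qs))
        counts["queries"] = {h: len(qs) for h, qs in queries.items()}
        qpath = os.path.join(config.out_dir, "queries.tsv")
        pd.DataFrame(query_rows).to_csv(qpath, sep="\t", index=False)
        outputs["queries.tsv"] = qpath

        stage = "build_library"
        min_len = min(len(s) for s in segments.values())
        library = fs.build_library(_load_library_structures(config.library_paths), min_chain_length=min_len)
        counts["library"] = {
            "chains": len(library.entries),
            "dropped_short": library.dropped_chains,
        }

        stage = "search"
        profiles: dict[str, fs.RMSDProfile] = {}
        for helix_id, qs in queries.items():
            profiles[helix_id] = fs.search(
                qs,
                library,
                top_k=config.top_k,
                directions=config.directions,
                identity_filter=config.identity_filter,
                require_helix=config.require_helix,
            )
        counts["search"] = {
            h: {
                "windows_scored": p.n_windows_scored,
                "matches_kept": len(p.matches),
                "skips": p.skip_histogram,
                "best_rmsd": round(p.best().rmsd, 6),
            }
            for h, p in profiles.items()
        }
        mpath = os.path.join(config.out_dir, "matches.tsv")
        _matches_frame(profiles).to_csv(mpath, sep="\t", index=False)
        outputs["matches.tsv"] = mpath

        stage = "assemble"
        plan = config.plan or asm.default_plan(
            {h: (s.start_seq_id, s.end_seq_id) for h, s in segments.items()}
        )
        best = {h: p.best() for h, p in profiles.items()}
        peptide = asm.assemble(best, plan, library, segments)
        counts["assembly"] = {
            "n_residues": len(peptide),
            "clash_count": peptide.geometry["clash_count"],
            "junction_violations": len(peptide.geometry["junction_violations"]),
            "handedness_uniform": peptide.geometry["handedness"]["uniform"],
        }

        ppath = os.path.join(config.out_dir, "assembled.pdb")
        sio.write_structure(peptide.to_structure(), ppath, d_naming=config.d_naming)
        outputs["assembled.pdb"] = ppath

        prov_path = os.path.join(config.out_dir, "provenance.tsv")
        pd.DataFrame([dataclasses.asdict(p) for p in peptide.provenance]).to_csv(
            prov_path, sep="\t", index=False
        )
        outputs["provenance.tsv"] = prov_path

        gpath = os.path.join(config.out_dir, "geometry.json")
        with open(gpath, "w") as fh:
            json.dump(peptide.geometry, fh, indent=1, sort_keys=True)
        outputs["geometry.json"] = gpath
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    manifest = {
        "stages": counts,
        "outputs": {name: {"path": path, "sha256": _sha256(path)} for name, path in outputs.items()},
        "plan": [list(c) for c in plan.contributions],
    }
    man_path = os.path.join(config.out_dir, "manifest.json")
    with open(man_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    logger.info("design run complete: %s", man_path)
    return {
        "scaffold": scaffold,
        "segments": segments,
        "queries": queries,
        "library": library,
        "profiles": profiles,
        "plan": plan,
        "peptide": peptide,
        "manifest": manifest,
        "out_dir": config.out_dir,
    }
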