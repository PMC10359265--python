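"""File I/O, run configuration and the batch pipeline.

Meshes are exchanged as STL/PLY/OBJ; the package's native interchange
format is ASCII PLY because it preserves vertex order and isolated
(landmark-only) vertices, both required for nodal correspondence with a
template registry. OBJ is read and written by a minimal parser for the
same reason. STL stores bare triangles (vertex identity and isolated
vertices are lost), so STL input is welded back to unique vertices in
first-appearance order and accepted only when that recovers the registry's
template vertex count.

Batches are manifest-driven: a CSV with one row per bone instance
(case_id, bone, side, mesh_path, registry_path, sex, age_years, height_cm)
keeps provenance explicit. Per-row failures are logged and reported in an
errors sidecar without aborting the batch.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .anatomy import CorrespondenceError, LandmarkRegistry, TriangleMesh
from .measurements import (
    BONE_MEASUREMENTS,
    MEASUREMENT_NAMES,
    measure_bone,
)

logger = logging.getLogger("bonemorph")

MESH_EXTENSIONS = (".stl", ".ply", ".obj")
MANIFEST_COLUMNS = ("case_id", "bone", "side", "mesh_path", "registry_path",
                    "sex", "age_years", "height_cm")
META_COLUMNS = ("case_id", "bone", "side", "sex", "age_years", "height_cm")


class MeshParseError(ValueError):
    """Mesh file unreadable or malformed; carries file and reason."""


class ValidationError(ValueError):
    """Tabular input violates the expected schema."""


class BatchError(RuntimeError):
    """More than half of the manifest rows failed."""


@dataclass
class RunConfig:
    """Pipeline configuration.

    alpha is the significance level of the per-category sex comparisons;
    mirror_left controls normalisation of left bones to the right-side sign
    convention; collapse_sides averages L/R rows per case before statistics.
    """

    output_dir: Path = Path(".")
    mirror_left: bool = True
    collapse_sides: bool = False
    alpha: float = 0.05
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        self.output_dir = Path(self.output_dir)
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


def configure_logging(config: RunConfig, log_name: str = "run.log") -> None:
    """Log to stderr and to a file in the output directory."""
    logger.setLevel(config.log_level.upper())
    logger.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for h in (logging.StreamHandler(sys.stderr),
              logging.FileHandler(config.output_dir / log_name)):
        h.setFormatter(fmt)
        logger.addHandler(h)


# ---------------------------------------------------------------------------
# Mesh I/O
# ---------------------------------------------------------------------------

def _weld_first_occurrence(vertices: np.ndarray, faces: np.ndarray):
    """Merge exactly-equal vertices, keeping first-appearance order."""
    seen: dict[bytes, int] = {}
    remap = np.empty(len(vertices), dtype=np.int64)
    unique = []
    for i, v in enumerate(vertices):
        key = v.tobytes()
        if key not in seen:
            seen[key] = len(unique)
            unique.append(v)
        remap[i] = seen[key]
    return np.asarray(unique), remap[faces]


def read_mesh(path, expected_vertex_count: int | None = None) -> TriangleMesh:
    """Read an STL/PLY/OBJ mesh into a :class:`TriangleMesh`.

    Vertex order is preserved for PLY and OBJ. STL input is welded to
    unique vertices in first-appearance order; when
    ``expected_vertex_count`` is given (the registry's template count) and
    neither the raw nor the welded count matches, a
    :class:`~bonemorph.anatomy.CorrespondenceError` is raised.
    """
    path = Path(path)
    if not path.exists():
        raise MeshParseError(f"{path}: file does not exist")
    ext = path.suffix.lower()
    if ext not in MESH_EXTENSIONS:
        raise MeshParseError(f"{path}: unsupported extension {ext!r}")
    try:
        if ext == ".obj":
            vertices, faces = _read_obj(path)
        else:
            import trimesh

            m = trimesh.load(path, file_type=ext[1:], process=False)
            vertices = np.asarray(m.vertices, dtype=float)
            faces = np.asarray(m.faces, dtype=np.int64).reshape(-1, 3)
        if len(vertices) < 4:
            raise ValueError("fewer than 4 vertices")
        mesh = TriangleMesh(vertices=vertices, faces=faces)
    except (MeshParseError, CorrespondenceError):
        raise
    except Exception as exc:
        raise MeshParseError(f"{path}: {exc}") from exc

    if ext == ".stl" or (expected_vertex_count is not None
                         and mesh.n_vertices != expected_vertex_count):
        if expected_vertex_count is not None and mesh.n_vertices != expected_vertex_count:
            v, f = _weld_first_occurrence(mesh.vertices, mesh.faces)
            if len(v) == expected_vertex_count:
                mesh = TriangleMesh(vertices=v, faces=f)
            else:
                raise CorrespondenceError(
                    f"{path}: {mesh.n_vertices} vertices ({len(v)} after welding) "
                    f"but registry expects {expected_vertex_count}")
    return mesh


def write_mesh(mesh: TriangleMesh, path) -> None:
    """Write a mesh as ASCII PLY, OBJ or STL.

    PLY and OBJ preserve vertex order and isolated vertices and are
    byte-deterministic. STL keeps triangles only: isolated landmark
    vertices are silently dropped, so STL output is unsuitable for
    correspondence-based landmarking of landmark-bearing meshes.
    """
    path = Path(path)
    ext = path.suffix.lower()
    v, f = mesh.vertices, mesh.faces
    if ext == ".ply":
        with open(path, "w") as fh:
            fh.write("ply\nformat ascii 1.0\n")
            fh.write(f"element vertex {len(v)}\n")
            fh.write("property double x\nproperty double y\nproperty double z\n")
            fh.write(f"element face {len(f)}\n")
            fh.write("property list uchar int vertex_indices\nend_header\n")
            for p in v:
                fh.write(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
            for tri in f:
                fh.write(f"3 {tri[0]} {tri[1]} {tri[2]}\n")
    elif ext == ".obj":
        with open(path, "w") as fh:
            for p in v:
                fh.write(f"v {p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
            for tri in f:
                fh.write(f"f {tri[0] + 1} {tri[1] + 1} {tri[2] + 1}\n")
    elif ext == ".stl":
        with open(path, "w") as fh:
            fh.write("solid bonemorph\n")
            for tri in f:
                a, b, c = v[tri[0]], v[tri[1]], v[tri[2]]
                n = np.cross(b - a, c - a)
                norm = np.linalg.norm(n)
                n = n / norm if norm > 0 else n
                fh.write(f"  facet normal {n[0]:.9g} {n[1]:.9g} {n[2]:.9g}\n")
                fh.write("    outer loop\n")
                for p in (a, b, c):
                    fh.write(f"      vertex {p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
                fh.write("    endloop\n  endfacet\n")
            fh.write("endsolid bonemorph\n")
    else:
        raise ValueError(f"unsupported mesh extension {ext!r}")


def _read_obj(path) -> tuple[np.ndarray, np.ndarray]:
    """Minimal OBJ parser keeping all vertices (also unreferenced ones)."""
    verts, faces = [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if parts[0] == "v":
                if len(parts) < 4:
                    raise MeshParseError(f"{path}:{ln}: malformed vertex line")
                verts.append([float(x) for x in parts[1:4]])
            elif parts[0] == "f":
                idx = [int(tok.split("/")[0]) for tok in parts[1:]]
                if len(idx) != 3:
                    raise MeshParseError(f"{path}:{ln}: only triangle faces supported")
                faces.append([i - 1 for i in idx])
    if not verts:
        raise MeshParseError(f"{path}: no vertices found")
    return (np.asarray(verts, dtype=float),
            np.asarray(faces, dtype=np.int64).reshape(-1, 3))


# ---------------------------------------------------------------------------
# Batch measurement
# ---------------------------------------------------------------------------

def _records_to_frame(records) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"case_id": r.case_id, "bone": r.bone, "side": r.side,
               "sex": r.sex, "age_years": r.age_years, "height_cm": r.height_cm}
        for name in MEASUREMENT_NAMES:
            row[name] = r.values.get(name, np.nan)
        rows.append(row)
    return pd.DataFrame(rows, columns=list(META_COLUMNS) + list(MEASUREMENT_NAMES))


def _attach_rotational_profile(df: pd.DataFrame) -> pd.DataFrame:
    """RP = TT - AA per (case, side), written onto the tibia row."""
    femur = df[df["bone"] == "femur"].set_index(["case_id", "side"])
    tibia_mask = df["bone"] == "tibia_fibula"
    for i in df.index[tibia_mask]:
        key = (df.at[i, "case_id"], df.at[i, "side"])
        if key in femur.index:
            aa = femur.at[key, "anteversion_angle"]
            df.at[i, "rotational_profile"] = df.at[i, "tibial_torsion"] - aa
    return df


def run_measure(manifest, config: RunConfig | None = None
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Measure every bone instance in a manifest.

    ``manifest`` is a CSV path or DataFrame with columns
    case_id, bone, side, mesh_path, registry_path, sex, age_years,
    height_cm. Relative mesh/registry paths resolve against the manifest's
    directory. Returns (measurements, errors); failures are isolated per
    row. Raises :class:`BatchError` when more than half the rows fail, and
    :class:`ValidationError` on an empty or malformed manifest.
    """
    config = config or RunConfig()
    if isinstance(manifest, (str, Path)):
        base = Path(manifest).parent
        manifest = pd.read_csv(manifest, dtype={"case_id": str})
    else:
        base = Path(".")
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValidationError(f"manifest missing columns: {missing}")
    if len(manifest) == 0:
        raise ValidationError("manifest is empty")

    import time

    records, errors = [], []
    for _, row in manifest.iterrows():
        t0 = time.perf_counter()
        try:
            reg_path = Path(row["registry_path"])
            if not reg_path.is_absolute():
                reg_path = base / reg_path
            registry = LandmarkRegistry.from_json(reg_path)
            mesh_path = Path(row["mesh_path"])
            if not mesh_path.is_absolute():
                mesh_path = base / mesh_path
            mesh = read_mesh(mesh_path,
                             expected_vertex_count=registry.template_vertex_count)
            rec = measure_bone(
                mesh, registry, case_id=str(row["case_id"]),
                side=str(row["side"]), sex=row.get("sex"),
                age_years=int(row["age_years"]) if pd.notna(row["age_years"]) else None,
                height_cm=float(row["height_cm"]) if pd.notna(row["height_cm"]) else None,
                mirror_left=config.mirror_left)
            records.append(rec)
            logger.info("measured %s %s/%s in %.2f s", row["case_id"],
                        row["bone"], row["side"], time.perf_counter() - t0)
        except Exception as exc:
            errors.append({"case_id": row["case_id"], "bone": row["bone"],
                           "side": row["side"], "error": f"{type(exc).__name__}: {exc}"})
            logger.warning("row failed: %s %s/%s: %s", row["case_id"],
                           row["bone"], row["side"], exc)

    df = _records_to_frame(records)
    if len(df):
        df = _attach_rotational_profile(df)
        df = df.sort_values(["case_id", "bone", "side"], kind="stable",
                            ignore_index=True)
    err_df = pd.DataFrame(errors, columns=["case_id", "bone", "side", "error"])
    if len(errors) * 2 > len(manifest):
        raise BatchError(
            f"{len(errors)} of {len(manifest)} manifest rows failed")
    return df, err_df


def write_measurement_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# Statistics runner
# ---------------------------------------------------------------------------

def validate_measurement_table(df: pd.DataFrame) -> None:
    """Schema check for a measurement table; raises ValidationError."""
    required = list(META_COLUMNS) + list(MEASUREMENT_NAMES)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"measurement table missing columns: {missing}")
    if len(df) == 0:
        raise ValidationError("measurement table is empty")
    bad_sex = set(df["sex"].dropna().unique()) - {"F", "M"}
    if bad_sex:
        raise ValidationError(f"invalid sex values: {sorted(bad_sex)} "
                              "(column 'sex' must be 'F' or 'M')")
    bad_bone = set(df["bone"].dropna().unique()) - {"pelvis", "femur", "tibia_fibula"}
    if bad_bone:
        raise ValidationError(f"invalid bone values: {sorted(bad_bone)}")


def _collapse_sides(df: pd.DataFrame) -> pd.DataFrame:
    """Average L/R rows per (case, bone); demographics taken from the first."""
    meta = [c for c in META_COLUMNS if c != "side"]
    agg = {c: "first" for c in ("sex", "age_years", "height_cm")}
    agg.update({m: "mean" for m in MEASUREMENT_NAMES})
    out = (df.groupby(["case_id", "bone"], as_index=False, observed=True)
             .agg(agg))
    out["side"] = "R"
    return out[list(META_COLUMNS) + list(MEASUREMENT_NAMES)]


def run_stats(measurements, config: RunConfig | None = None,
              covariates: tuple[str, ...] = ("age", "height")) -> dict:
    """Summaries, growth regressions and two-way ANOVAs for a cohort table.

    Writes summary.csv, regression.csv, anova.csv and anova.json to the
    configured output directory and returns the artefacts in memory.
    """
    from . import __version__
    from .growth_stats import (
        assign_bins, fit_growth_regression, group_summary, two_way_anova,
    )

    config = config or RunConfig()
    if isinstance(measurements, (str, Path)):
        df = pd.read_csv(measurements, dtype={"case_id": str})
    else:
        df = measurements.copy()
    validate_measurement_table(df)
    if config.collapse_sides:
        df = _collapse_sides(df)

    outdir = config.output_dir
    outdir.mkdir(parents=True, exist_ok=True)
    configure_logging(config, "stats_run.log")
    logger.info("run_stats: seed=%d rows=%d collapse_sides=%s bonemorph=%s "
                "pandas=%s", config.seed, len(df), config.collapse_sides,
                __version__, pd.__version__)

    summaries, regressions, anova_rows, anova_json = [], [], [], {}
    for covariate in covariates:
        binned = assign_bins(df, covariate)
        cat_col = f"{covariate}_category"
        for name in MEASUREMENT_NAMES:
            sub = binned[binned[name].notna()]
            if sub.empty:
                continue
            s = group_summary(sub, name, cat_col)
            s.insert(0, "measurement", name)
            s.insert(1, "covariate", covariate)
            s = s.rename(columns={cat_col: "category"})
            summaries.append(s)
            try:
                r = fit_growth_regression(sub, name, covariate)
                regressions.append({
                    "measurement": name, "covariate": covariate,
                    "slope": r.slope, "intercept": r.intercept,
                    "R": r.R, "p_value": r.p_value, "n": r.n})
            except ValueError as exc:
                logger.warning("regression skipped for %s/%s: %s",
                               name, covariate, exc)
            try:
                a = two_way_anova(sub, name, cat_col)
            except ValueError as exc:
                logger.warning("ANOVA skipped for %s/%s: %s", name, covariate, exc)
                continue
            for eff, d in a.effects.items():
                anova_rows.append({"measurement": name, "covariate": covariate,
                                   "effect": eff, **d})
            anova_json[f"{name}|{covariate}"] = {
                "effects": a.effects,
                "reduced_model": a.reduced_model,
                "sex_comparisons": [vars(c) for c in a.sex_comparisons],
            }

    summary_df = (pd.concat(summaries, ignore_index=True)
                  if summaries else pd.DataFrame())
    regression_df = pd.DataFrame(regressions)
    anova_df = pd.DataFrame(anova_rows)
    summary_df.to_csv(outdir / "summary.csv", index=False)
    regression_df.to_csv(outdir / "regression.csv", index=False)
    anova_df.to_csv(outdir / "anova.csv", index=False)
    with open(outdir / "anova.json", "w") as fh:
        json.dump(anova_json, fh, indent=1, default=float)
    return {"summary": summary_df, "regression": regression_df,
            "anova": anova_df, "anova_detail": anova_json}
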