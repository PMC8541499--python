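"""Two-variant comparison: the model/results interface of the package.

:class:`PhosphoComparison` is built from two conformational ensembles — the
non-phosphorylated and phosphorylated variant of the same peptide — and a
:class:`ComparisonConfig` holding every tunable of the analysis stages.
Its :meth:`~PhosphoComparison.fit` runs the full pipeline

    dimensions -> secondary structure -> contacts -> salt bridges
    -> cation-pi -> shared-basis energy landscapes

with identical parameters for both variants and returns a
:class:`ComparisonResults` carrying the estimates, their block/replicate
errors, a text :meth:`~ComparisonResults.summary` and
:meth:`~ComparisonResults.save_tables` for machine-readable reports.  The
pipeline is deterministic and never mutates its input ensembles.

Ensembles without a full backbone (e.g. bead-chain polymer models) are
still accepted: stages that need backbone or hydrogen atoms are skipped
with a recorded warning, so polymer-reference comparisons work end to end.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from pydantic import BaseModel

from ._errors import ConfensError, InputError
from .dimensions import (
    BlockAverageResult,
    block_average_error,
    end_to_end_distance,
    kde_distribution,
    radius_of_gyration,
    shape_factor,
)
from .interactions import (
    InteractionTable,
    cation_pi_table,
    contact_delta,
    contact_map,
    salt_bridge_table,
)
from .io import ConformationalEnsemble, read_multimodel_pdb, subsample_frames
from .landscape import find_basins, free_energy_surface, shared_pca
from .secondary import PPIIWindow, assign_with_ppii, ss_profile

logger = logging.getLogger("confens")

__all__ = ["ComparisonConfig", "PhosphoComparison", "ComparisonResults"]


@dataclass
class ComparisonConfig:
    """Every tunable of the two-variant pipeline, recorded in each report."""

    n_frames: int | None = None  # equal-spacing subsample target (None = all)
    endpoint_atom: str = "CA"
    rs_convention: str = "mean-square"
    contact_cutoff: float = 0.4  # nm
    contact_heavy_only: bool = True
    ppii_phi: float = -75.0
    ppii_psi: float = 145.0
    ppii_tolerance: float = 29.0
    ppii_min_run: int = 2
    hb_r0: float = 0.33  # nm
    hb_k: float = 0.00044  # nm/deg^2
    include_carboxylates: bool = False
    cation_atom: str = "CZ"
    cation_pi_cutoff: float = 0.6  # nm
    pca_mode: str = "pooled"
    landscape_grid: int = 200
    landscape_max_level: float = 5.0  # RT

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_file(cls, path: str | Path) -> "ComparisonConfig":
        """Flat ``key: value`` text config; unknown keys are rejected."""
        values: dict[str, Any] = {}
        fields = {f: t for f, t in cls.__dataclass_fields__.items()}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, sep, raw = line.partition(":")
            key = key.strip()
            if not sep or key not in fields:
                raise InputError(f"{path}:{lineno}: unknown config key {key!r}")
            raw = raw.strip()
            if raw.lower() in ("none", ""):
                values[key] = None
            elif raw.lower() in ("true", "false"):
                values[key] = raw.lower() == "true"
            else:
                try:
                    values[key] = int(raw)
                except ValueError:
                    try:
                        values[key] = float(raw)
                    except ValueError:
                        values[key] = raw
        return cls(**values)


class _StageTimer:
    def __init__(self, name: str, sink: list[str]):
        self.name, self.sink = name, sink

    def __enter__(self):
        self.t0 = time.perf_counter()
        logger.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None:
            raise ConfensError(f"stage {self.name!r} failed: {exc}") from exc
        logger.info("stage %s: done in %.2f s", self.name, time.perf_counter() - self.t0)


def _has_full_backbone(ensemble: ConformationalEnsemble) -> bool:
    topo = ensemble.topology
    for r in range(topo.n_residues):
        names = set(topo.atom_names[topo.atom_indices(residue=r)])
        if not {"N", "CA", "C", "O"} <= names:
            return False
    return True


class PhosphoComparison:
    """Model: a non-phosphorylated / phosphorylated ensemble pair.

    Parameters
    ----------
    nonphos, phos:
        The two ensemble variants; they must have the same residue count
        (the phosphorylated variant differs only in side-chain chemistry).
    config:
        Analysis parameters; defaults reproduce the standard conventions
        (0.4 nm contacts, Wernet-Nilsson hydrogen bonds, CZ cation centre,
        pooled-basis PCA, 200x200 landscape grid).
    """

    def __init__(
        self,
        nonphos: ConformationalEnsemble,
        phos: ConformationalEnsemble,
        config: ComparisonConfig | None = None,
    ):
        if nonphos.n_residues != phos.n_residues:
            raise InputError(
                f"variants have different residue counts: "
                f"{nonphos.n_residues} vs {phos.n_residues}"
            )
        self.config = config or ComparisonConfig()
        if self.config.n_frames is not None:
            nonphos = subsample_frames(nonphos, self.config.n_frames)
            phos = subsample_frames(phos, self.config.n_frames)
        self.nonphos = nonphos
        self.phos = phos

    @classmethod
    def from_pdb_files(
        cls,
        nonphos_path: str | Path,
        phos_path: str | Path,
        config: ComparisonConfig | None = None,
    ) -> "PhosphoComparison":
        return cls(
            read_multimodel_pdb(nonphos_path),
            read_multimodel_pdb(phos_path),
            config,
        )

    @property
    def variants(self) -> dict[str, ConformationalEnsemble]:
        return {"nonphos": self.nonphos, "phos": self.phos}

    def fit(self) -> "ComparisonResults":
        cfg = self.config
        collected: list[str] = []

        def _warn(msg: str) -> None:
            collected.append(msg)
            logger.warning("%s", msg)

        dimensions_rows = {}
        kde_curves: dict[str, dict] = {}
        with _StageTimer("dimensions", collected):
            for name, ens in self.variants.items():
                rg = radius_of_gyration(ens)
                ree = end_to_end_distance(ens, atom=cfg.endpoint_atom)
                with warnings.catch_warnings(record=True) as caught:
                    warnings.simplefilter("always")
                    rg_bar = block_average_error(rg)
                    ree_bar = block_average_error(ree)
                    if cfg.rs_convention == "mean-square":
                        rs = shape_factor(
                            block_average_error(rg**2),
                            block_average_error(ree**2),
                            cfg.rs_convention,
                        )
                    else:
                        rs = shape_factor(rg_bar, ree_bar, cfg.rs_convention)
                for w in caught:
                    _warn(f"{name}: {w.message}")
                if not (rg_bar.converged and ree_bar.converged):
                    _warn(f"{name}: block-average error estimate unconverged")
                dimensions_rows[name] = {
                    "rg_nm": rg_bar.mean,
                    "rg_err_nm": rg_bar.error,
                    "ree_nm": ree_bar.mean,
                    "ree_err_nm": ree_bar.error,
                    "rs": rs.rs,
                    "rs_err": rs.error,
                }
                kde_curves[name] = {
                    "rg": kde_distribution(rg),
                    "ree": kde_distribution(ree),
                }
        dimensions = pd.DataFrame.from_dict(dimensions_rows, orient="index")
        dimensions.index.name = "variant"

        ss_profiles: dict[str, Any] = {}
        full_backbone = all(_has_full_backbone(e) for e in self.variants.values())
        window = PPIIWindow(
            cfg.ppii_phi, cfg.ppii_psi, cfg.ppii_tolerance, cfg.ppii_min_run
        )
        if full_backbone:
            with _StageTimer("secondary_structure", collected):
                for name, ens in self.variants.items():
                    ss_profiles[name] = ss_profile(assign_with_ppii(ens, window))
        else:
            _warn("secondary structure skipped: incomplete backbone atoms")

        with _StageTimer("contacts", collected):
            maps = {
                name: contact_map(ens, cfg.contact_cutoff, cfg.contact_heavy_only)
                for name, ens in self.variants.items()
            }
            delta = contact_delta(maps["phos"], maps["nonphos"])

        salt_bridges: dict[str, InteractionTable] = {}
        with _StageTimer("salt_bridges", collected):
            for name, ens in self.variants.items():
                with warnings.catch_warnings(record=True) as caught:
                    warnings.simplefilter("always")
                    salt_bridges[name] = salt_bridge_table(
                        ens,
                        include_carboxylates=cfg.include_carboxylates,
                        r0=cfg.hb_r0,
                        k=cfg.hb_k,
                    )
                for w in caught:
                    _warn(f"{name}: {w.message}")

        cation_pi: dict[str, InteractionTable] = {}
        with _StageTimer("cation_pi", collected):
            for name, ens in self.variants.items():
                cation_pi[name] = cation_pi_table(
                    ens, cfg.cation_atom, cfg.cation_pi_cutoff
                )

        landscapes: dict[str, Any] = {}
        basins: dict[str, list] = {}
        basis = None
        if min(e.n_frames for e in self.variants.values()) >= 100:
            with _StageTimer("landscape", collected):
                basis, proj_a, proj_b = shared_pca(
                    self.nonphos, self.phos, mode=cfg.pca_mode
                )
                for name, proj in (("nonphos", proj_a), ("phos", proj_b)):
                    surf = free_energy_surface(
                        proj,
                        grid_size=cfg.landscape_grid,
                        replicate_id=self.variants[name].replicate_id,
                    )
                    landscapes[name] = surf
                    with warnings.catch_warnings(record=True) as caught:
                        warnings.simplefilter("always")
                        basins[name] = find_basins(surf, cfg.landscape_max_level)
                    for w in caught:
                        _warn(f"{name}: {w.message}")
        else:
            _warn("landscape skipped: fewer than 100 frames per variant")

        return ComparisonResults(
            config=cfg,
            dimensions=dimensions,
            kde=kde_curves,
            ss_profiles=ss_profiles,
            contact_maps=maps,
            contact_change=delta,
            salt_bridges=salt_bridges,
            cation_pi=cation_pi,
            pc_basis=basis,
            landscapes=landscapes,
            basins=basins,
            warnings=collected,
        )


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------


class BasinRecord(BaseModel):
    basin_id: int
    min_pc1: float
    min_pc2: float
    min_free_energy_rt: float
    population: float
    energy_class: str | None
    representative_frame: int | None


class VariantRecord(BaseModel):
    rg_nm: float
    rg_err_nm: float
    ree_nm: float
    ree_err_nm: float
    rs: float
    rs_err: float
    n_frames: int | None = None


class ReportDocument(BaseModel):
    """Schema of the machine-readable ``report.json``."""

    config: dict[str, Any]
    dimensions: dict[str, VariantRecord]
    salt_bridges: dict[str, list[dict[str, Any]]]
    cation_pi: dict[str, list[dict[str, Any]]]
    basins: dict[str, list[BasinRecord]]
    warnings: list[str]


@dataclass
class ComparisonResults:
    """Fitted two-variant comparison: estimates, errors, diagnostics."""

    config: ComparisonConfig
    dimensions: pd.DataFrame
    kde: dict[str, dict]
    ss_profiles: dict[str, Any]
    contact_maps: dict[str, Any]
    contact_change: np.ndarray
    salt_bridges: dict[str, InteractionTable]
    cation_pi: dict[str, InteractionTable]
    pc_basis: Any
    landscapes: dict[str, Any]
    basins: dict[str, list]
    warnings: list[str] = field(default_factory=list)

    @property
    def ss_delta(self) -> pd.DataFrame | None:
        """Per-residue change of grouped-class fractions (phos - nonphos)."""
        if not self.ss_profiles:
            return None
        return (
            self.ss_profiles["phos"].per_residue
            - self.ss_profiles["nonphos"].per_residue
        )

    def summary(self) -> str:
        lines = ["Two-variant conformational-ensemble comparison", "=" * 47, ""]
        lines.append("Global dimensions (mean +/- block error):")
        for variant, row in self.dimensions.iterrows():
            lines.append(
                f"  {variant:8s} Rg = {row.rg_nm:.3f} +/- {row.rg_err_nm:.3f} nm   "
                f"Ree = {row.ree_nm:.3f} +/- {row.ree_err_nm:.3f} nm   "
                f"rs = {row.rs:.2f} +/- {row.rs_err:.2f}"
            )
        if self.ss_profiles:
            lines.append("")
            lines.append("Mean secondary-structure content (fractions):")
            for variant, prof in self.ss_profiles.items():
                parts = "  ".join(
                    f"{grp}={val:.3f}" for grp, val in prof.content.items()
                )
                lines.append(f"  {variant:8s} {parts}")
        for kind, tables in (
            ("Salt bridges", self.salt_bridges),
            ("Cation-pi", self.cation_pi),
        ):
            rows = sum(len(t.table) for t in tables.values())
            if rows:
                lines.append("")
                lines.append(f"{kind} (probability % +/- replicate SE):")
                for variant, t in tables.items():
                    for _, r in t.table.iterrows():
                        err = "n/a" if np.isnan(r.error_pct) else f"{r.error_pct:.1f}"
                        lines.append(
                            f"  {variant:8s} {r.donor:>6s} -> {r.acceptor:<6s} "
                            f"{r.probability_pct:5.1f} +/- {err}"
                        )
        if self.basins:
            lines.append("")
            lines.append("Free-energy basins (population, min F in RT):")
            for variant, blist in self.basins.items():
                for k, b in enumerate(blist):
                    lines.append(
                        f"  {variant:8s} basin {k}: pop={b.population:.3f} "
                        f"Fmin={b.minimum_energy:.2f} RT ({b.energy_class})"
                    )
        if self.warnings:
            lines.append("")
            lines.append("Warnings:")
            lines.extend(f"  - {w}" for w in self.warnings)
        return "\n".join(lines)

    # -- reports ---------------------------------------------------------

    def report_document(self) -> ReportDocument:
        basins = {
            variant: [
                BasinRecord(
                    basin_id=k,
                    min_pc1=b.minimum[0],
                    min_pc2=b.minimum[1],
                    min_free_energy_rt=b.minimum_energy,
                    population=b.population,
                    energy_class=b.energy_class,
                    representative_frame=b.representative_frame,
                )
                for k, b in enumerate(blist)
            ]
            for variant, blist in self.basins.items()
        }
        def _records(t: InteractionTable) -> list[dict[str, Any]]:
            recs = t.table.to_dict(orient="records")
            for r in recs:
                if isinstance(r.get("error_pct"), float) and np.isnan(r["error_pct"]):
                    r["error_pct"] = None
            return recs

        return ReportDocument(
            config=self.config.to_dict(),
            dimensions={
                v: VariantRecord(**row) for v, row in self.dimensions.iterrows()
            },
            salt_bridges={v: _records(t) for v, t in self.salt_bridges.items()},
            cation_pi={v: _records(t) for v, t in self.cation_pi.items()},
            basins=basins,
            warnings=list(self.warnings),
        )

    def save_tables(self, out_dir: str | Path) -> None:
        """Write all tables as CSV plus a schema-validated ``report.json``.

        Output is byte-identical across reruns on the same inputs/config.
        """
        out = Path(out_dir)
        try:
            out.mkdir(parents=True, exist_ok=True)
        except OSError as exc:
            raise OSError(f"cannot create output directory {out}: {exc}") from exc
        self.dimensions.to_csv(out / "dimensions.csv", float_format="%.6g")
        for variant in self.kde:
            for quantity, est in self.kde[variant].items():
                pd.DataFrame({"grid": est.grid, "density": est.density}).to_csv(
                    out / f"kde_{variant}_{quantity}.csv",
                    index=False,
                    float_format="%.6g",
                )
        for variant, prof in self.ss_profiles.items():
            prof.per_residue.to_csv(
                out / f"ss_profile_{variant}.csv", float_format="%.6g"
            )
        for variant, cmap in self.contact_maps.items():
            np.savetxt(
                out / f"contact_map_{variant}.csv", cmap.probability,
                delimiter=",", fmt="%.6g",
            )
        np.savetxt(
            out / "contact_delta.csv", self.contact_change, delimiter=",", fmt="%.6g"
        )
        for variant, t in self.salt_bridges.items():
            t.table.to_csv(
                out / f"salt_bridges_{variant}.csv", index=False, float_format="%.6g"
            )
        for variant, t in self.cation_pi.items():
            t.table.to_csv(
                out / f"cation_pi_{variant}.csv", index=False, float_format="%.6g"
            )
        for variant, surf in self.landscapes.items():
            np.savetxt(
                out / f"landscape_{variant}.csv", surf.free_energy,
                delimiter=",", fmt="%.6g",
            )
            pd.DataFrame(
                {
                    "pc1": surf.projections[:, 0],
                    "pc2": surf.projections[:, 1],
                }
            ).to_csv(
                out / f"projections_{variant}.csv", index=False, float_format="%.6g"
            )
        for variant, blist in self.basins.items():
            pd.DataFrame(
                [
                    {
                        "basin_id": k,
                        "min_pc1": b.minimum[0],
                        "min_pc2": b.minimum[1],
                        "min_F_RT": b.minimum_energy,
                        "population": b.population,
                        "energy_class": b.energy_class,
                        "representative_frame": b.representative_frame,
                    }
                    for k, b in enumerate(blist)
                ]
            ).to_csv(out / f"basins_{variant}.csv", index=False, float_format="%.6g")
        doc = self.report_document()
        (out / "report.json").write_text(
            json.dumps(doc.model_dump(), indent=1, sort_keys=True) + "\n"
        )


def run_comparison(
    config: ComparisonConfig,
    ensemble_nonphos: ConformationalEnsemble,
    ensemble_phos: ConformationalEnsemble,
) -> ComparisonResults:
    """Functional entry point: build the model and fit it."""
    return PhosphoComparison(ensemble_nonphos, ensemble_phos, config).fit()


def render_tables(comparison: ComparisonResults, out_dir: str | Path) -> None:
    """Write the comparison's tables to ``out_dir`` (CSV + report.json)."""
    comparison.save_tables(out_dir)
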