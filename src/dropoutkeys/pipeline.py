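"""End-to-end orchestration: one config in, a reproducible report bundle out.

Wires the stages together in the order of the experimental analysis chain:
abundance loading -> strain relationships -> keystone summary -> ordination
-> metabolite calls -> ΔpH summary -> report manifest. Every stage writes
its table under the output directory; the manifest records versions, the
seed, a digest of all parameters, completed stages, and the audit counts a
reviewer would check (censored entries, dropped features, flagged outliers).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import io as dio
from .metabolites import FeatureMatrix, call_consumption_production, filter_features
from .relationships import delta_ph_summary, keystone_impact, relationship_matrix
from .structure import ordination
from .types import ValidationError

log = logging.getLogger("dropoutkeys")


@dataclass
class PipelineConfig:
    """Paths and parameters of one full analysis run."""

    abundance_path: str
    roster_path: str
    out_dir: str
    ph_path: str | None = None
    metabolite_path: str | None = None
    alpha: float = 0.05
    use_bh: bool = True
    aggregate_level: str = "well"  # or "bio"
    ordination_transform: str = "raw"  # or "log"
    ordination_groups: str = "environment"
    ordination_aggregate: str = "sample"  # or "median_community"
    n_perm: int = 999
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValidationError(f"alpha must lie in (0, 1), got {self.alpha}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def validate_paths(self) -> None:
        for name in ("abundance_path", "roster_path", "ph_path", "metabolite_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ValidationError(f"{name} does not exist: {p}")

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def run_full_analysis(config: PipelineConfig) -> dict:
    """Run every applicable stage; returns (and writes) the JSON manifest."""
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: list[str] = []
    audit: dict[str, int] = {}

    def stage(name):
        stages.append(name)
        log.info("stage %s complete", name)

    try:
        roster = dio.read_roster_config(config.roster_path)
        table = dio.read_abundance_table(config.abundance_path, roster)
        audit["n_samples"] = len(table.samples)
        audit["n_censored_entries"] = table.n_censored()
        stage("abundance")

        rel = relationship_matrix(
            table, alpha=config.alpha, level=config.aggregate_level
        )
        dio.write_relationship_table(rel, out / "relationships.csv")
        stage("relationships")

        key_rows = []
        for env in table.environments:
            for comm in table.communities:
                if not comm.startswith("minus_"):
                    continue
                imp = keystone_impact(
                    table,
                    comm.removeprefix("minus_"),
                    env,
                    alpha=config.alpha,
                    level=config.aggregate_level,
                )
                key_rows.append(
                    {
                        "focal_x": imp.focal_x,
                        "environment": imp.environment,
                        "n_affected": imp.n_affected,
                        "n_affected_wilcoxon": imp.n_affected_wilcoxon,
                        "n_affected_bh": imp.n_affected_bh,
                        "affected_set": ";".join(imp.affected_set),
                    }
                )
        keystones = pd.DataFrame(key_rows)
        dio._write_frame(keystones, out / "keystones.csv")
        stage("keystones")

        if config.ordination_aggregate == "median_community":
            wide = table.to_wide(aggregate="median_community")
            ok_groups = pd.Series(
                [i.split("|")[1] for i in wide.index], index=wide.index
            )
        else:
            wide = table.to_wide()
            ok_groups = table.sample_groups(config.ordination_groups).loc[wide.index]
        if config.ordination_transform == "log":
            from .structure import log_transform

            wide = log_transform(wide, roster.dtl_map())
        ord_res = ordination(
            wide,
            groups=ok_groups if ok_groups.nunique() >= 2 else None,
            n_perm=config.n_perm,
            seed=config.seed,
        )
        dio._write_frame(
            ord_res.bc_matrix.reset_index(), out / "bray_curtis.csv"
        )
        dio._write_frame(ord_res.coords.reset_index(), out / "pcoa_coords.csv")
        if ord_res.permanova is not None:
            dio._write_frame(ord_res.permanova, out / "permanova.csv")
        if ord_res.outlier_flags is not None:
            audit["n_ordination_outliers"] = int(ord_res.outlier_flags.sum())
            flags = ord_res.outlier_flags.rename("outlier").reset_index()
            flags.columns = ["sample_id", "outlier"]
            flags["group"] = ok_groups.loc[flags["sample_id"]].to_numpy()
            dio._write_frame(flags, out / "ordination_outliers.csv")
        stage("ordination")

        if config.metabolite_path is not None:
            m = pd.read_csv(config.metabolite_path)
            meta_cols = ["sample_id", "role", "community", "environment"]
            fm = FeatureMatrix(
                m.set_index("sample_id").drop(columns=[c for c in meta_cols[1:] if c in m]),
                m.set_index("sample_id")["role"],
                m.set_index("sample_id")["environment"] if "environment" in m else None,
                m.set_index("sample_id")["community"] if "community" in m else None,
            )
            fm, dropped = filter_features(fm)
            audit["n_features_dropped"] = len(dropped)
            calls = []
            envs = (
                sorted(fm.environments.unique()) if fm.environments is not None else [None]
            )
            for env in envs:
                c = call_consumption_production(fm, environment=env, alpha=config.alpha)
                c.insert(0, "environment", env if env is not None else "all")
                calls.append(c)
            dio._write_frame(pd.concat(calls, ignore_index=True), out / "metabolite_calls.csv")
            stage("metabolites")

        if config.ph_path is not None:
            ph = pd.read_csv(config.ph_path)
            summary = delta_ph_summary(ph, table.samples)
            dio._write_frame(summary, out / "delta_ph.csv")
            stage("ph")

        manifest = {
            "version": __version__,
            "seed": config.seed,
            "parameter_digest": config.digest(),
            "stages": stages + ["report"],
            "audit": audit,
        }
        manifest["manifest_digest"] = hashlib.sha256(
            json.dumps(manifest, sort_keys=True).encode()
        ).hexdigest()[:16]
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return manifest
    except Exception as err:
        raise RuntimeError(
            f"pipeline failed in stage {len(stages) + 1} "
            f"(completed: {stages}); input: {config.abundance_path}"
        ) from err
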