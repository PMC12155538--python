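"""Delimited-text readers and writers, run configuration and manifests.

Interchange formats are plain delimited text (comma for ``.csv``, tab
otherwise).  The outcome file has columns ``sample_id, time, status``;
genotype and covariate matrices have a ``sample_id`` column followed by
one column per variable, one row per sample.  Files are aligned by
``sample_id`` with a hard error on mismatch — no silent intersection.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd

from .credible_sets import CredibleSet
from .gibss import SusieFit
from .survival_core import SurvivalOutcome

__all__ = ["RunConfig", "read_outcome", "read_matrix", "read_inputs",
           "write_results", "write_outcome", "write_matrix"]


@dataclass
class RunConfig:
    """All tunables of a fine-mapping run, serialized into the manifest."""

    L: int = 10
    sigma0sq_init: float = 1.0
    estimate_sigma0: bool = True
    rho: float = 0.95
    min_purity: float = 0.5
    ties: str = "efron"
    max_iter: int = 100
    tol: float = 1e-3
    threads: int = 1
    seed: int = 0

    def validate(self) -> "RunConfig":
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if self.sigma0sq_init <= 0:
            raise ValueError("sigma0sq_init must be > 0")
        if not 0 < self.rho < 1:
            raise ValueError("rho must be in (0, 1)")
        if not 0 <= self.min_purity <= 1:
            raise ValueError("min_purity must be in [0, 1]")
        if self.ties not in ("efron", "breslow"):
            raise ValueError("ties must be 'efron' or 'breslow'")
        if self.max_iter < 1 or self.tol <= 0 or self.threads < 1:
            raise ValueError("max_iter, tol and threads must be positive")
        return self


def _sep(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_config_file(path) -> dict:
    """Parse a plain-text ``key = value`` configuration file.

    Blank lines and ``#`` comments are ignored; values are coerced to
    bool/int/float where they parse as such.
    """
    out: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', "
                             f"got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if value.lower() in ("true", "false"):
            out[key] = value.lower() == "true"
            continue
        for cast in (int, float):
            try:
                out[key] = cast(value)
                break
            except ValueError:
                continue
        else:
            out[key] = value
    return out


def read_outcome(path) -> tuple[pd.Index, SurvivalOutcome]:
    """Read sample IDs and survival outcomes from a delimited file."""
    df = pd.read_csv(path, sep=_sep(path))
    required = {"sample_id", "time", "status"}
    if not required.issubset(df.columns):
        raise ValueError(f"outcome file {path} must have columns "
                         f"{sorted(required)}")
    times = pd.to_numeric(df["time"], errors="coerce")
    status = pd.to_numeric(df["status"], errors="coerce")
    if times.isna().any() or status.isna().any():
        bad = df.loc[times.isna() | status.isna(), "sample_id"].iloc[0]
        raise ValueError(f"non-numeric time/status for sample {bad!r}")
    nonpos = times <= 0
    if nonpos.any():
        bad = df.loc[nonpos, "sample_id"].iloc[0]
        raise ValueError(f"non-positive time for sample {bad!r}")
    outcome = SurvivalOutcome(times=times.to_numpy(),
                              status=status.to_numpy().astype(np.int8))
    return pd.Index(df["sample_id"].astype(str)), outcome


def read_matrix(path) -> tuple[pd.Index, pd.DataFrame]:
    """Read a sample-by-variable matrix keyed by ``sample_id``."""
    df = pd.read_csv(path, sep=_sep(path))
    if "sample_id" not in df.columns:
        raise ValueError(f"matrix file {path} must have a sample_id column; "
                         "if variants are rows, transpose the file")
    ids = pd.Index(df["sample_id"].astype(str))
    mat = df.drop(columns=["sample_id"])
    for col in mat.columns:
        vals = pd.to_numeric(mat[col], errors="coerce")
        if vals.isna().any():
            row = int(np.flatnonzero(vals.isna())[0])
            raise ValueError(f"non-numeric or missing value in column "
                             f"{col!r}, row {row} of {path} "
                             "(missing genotypes are not imputed)")
        mat[col] = vals
    return ids, mat


def _align(ids_a: pd.Index, ids_b: pd.Index, what: str) -> np.ndarray:
    """Indices into b reordering it to a's sample order; error on mismatch."""
    if set(ids_a) != set(ids_b):
        missing = sorted(set(ids_a) ^ set(ids_b))[:5]
        raise ValueError(f"sample IDs differ between genotype and {what} "
                         f"files (e.g. {missing})")
    pos = pd.Series(np.arange(len(ids_b)), index=ids_b)
    return pos.loc[ids_a].to_numpy()


def read_inputs(genotype_path, outcome_path, covariate_path=None):
    """Load and sample-align genotype, outcome and optional covariates.

    Returns ``(X, variant_ids, outcome, Z, covariate_ids)`` with rows of
    every matrix in the genotype file's sample order.  Zero-variance
    variants are retained (the degenerate fit path handles them).
    """
    geno_ids, geno = read_matrix(genotype_path)
    out_ids, outcome = read_outcome(outcome_path)
    take = _align(geno_ids, out_ids, "outcome")
    outcome = SurvivalOutcome(times=outcome.times[take],
                              status=outcome.status[take])
    Z = cov_ids = None
    if covariate_path is not None:
        cids, cov = read_matrix(covariate_path)
        take_c = _align(geno_ids, cids, "covariate")
        Z = cov.to_numpy(dtype=np.float64)[take_c]
        cov_ids = list(cov.columns)
    return (geno.to_numpy(dtype=np.float64), list(geno.columns), outcome,
            Z, cov_ids)


def write_matrix(path, ids, matrix, columns) -> None:
    df = pd.DataFrame(np.asarray(matrix), columns=columns)
    df.insert(0, "sample_id", list(ids))
    df.to_csv(path, sep=_sep(path), index=False)


def write_outcome(path, ids, outcome: SurvivalOutcome) -> None:
    pd.DataFrame({"sample_id": list(ids), "time": outcome.times,
                  "status": outcome.status}).to_csv(path, sep=_sep(path),
                                                    index=False)


def pip_table(fit: SusieFit, variant_ids, include_alpha: bool = True
              ) -> pd.DataFrame:
    df = pd.DataFrame({"variant_id": variant_ids, "pip": fit.pip})
    if include_alpha:
        for l, ser in enumerate(fit.sers):
            df[f"alpha_L{l + 1}"] = ser.alpha
    return df


def cs_table(cs_list: list[CredibleSet], variant_ids,
             region_label: str = "region1") -> pd.DataFrame:
    rows = [{
        "region_label": region_label,
        "effect": cs.label,
        "size": cs.size,
        "purity": cs.purity,
        "sentinel_id": variant_ids[cs.sentinel],
        "sentinel_pip": cs.sentinel_pip,
        "members": ";".join(variant_ids[j] for j in cs.members),
        "attained_mass": cs.attained_mass,
    } for cs in cs_list]
    return pd.DataFrame(rows, columns=["region_label", "effect", "size",
                                       "purity", "sentinel_id",
                                       "sentinel_pip", "members",
                                       "attained_mass"])


def write_results(fit: SusieFit, cs_list: list[CredibleSet], variant_ids,
                  outdir, config: RunConfig | None = None) -> dict:
    """Write PIP table, CS table and a reproducibility manifest.

    Returns a dict of the paths written.  The manifest records the full
    run configuration, iteration count and convergence flag; replaying
    the same inputs with the manifest's config reproduces the tables
    byte for byte.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"pip": outdir / "pips.tsv", "cs": outdir / "credible_sets.tsv",
             "manifest": outdir / "manifest.json"}
    pip_table(fit, variant_ids).to_csv(paths["pip"], sep="\t", index=False)
    cs_table(cs_list, variant_ids).to_csv(paths["cs"], sep="\t", index=False)
    manifest = {
        "config": asdict(config) if config else None,
        "n_iter": fit.n_iter,
        "converged": bool(fit.converged),
        "sigma0sq": [float(v) for v in fit.sigma0sq],
        "null_effect": [bool(v) for v in fit.null_effect],
        "n_credible_sets": len(cs_list),
        "versions": {"python": platform.python_version(),
                     "numpy": np.__version__, "pandas": pd.__version__},
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2))
    return {k: str(v) for k, v in paths.items()}
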