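"""Tabular and sequence I/O, run configuration, and the pipeline driver.

All tables are tab-separated with named, schema-validated columns; residue
coordinates are 1-based inclusive, temperatures in degrees Celsius, growth
times in minutes and HDX timepoints in seconds.  Output files carry a header
comment naming the tool version, stage and config digest.  All randomness
flows from explicit config seeds.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SCHEMAS",
    "read_table",
    "write_table",
    "read_fasta",
    "write_fasta",
    "RunConfig",
    "run_pipeline",
]

# column -> (dtype, non-negative required)
SCHEMAS: dict[str, dict] = {
    "fractionation": {
        "protein_id": (str, False),
        "species": (str, False),
        "condition": (str, False),
        "temperature_c": (float, False),
        "replicate": (int, False),
        "total": (float, True),
        "sup": (float, True),
        "pellet": (float, True),
    },
    "growth": {
        "temperature_c": (float, False),
        "time_min": (float, True),
        "od600": (float, True),
    },
    "dls": {
        "protein": (str, False),
        "replicate": (int, False),
        "temperature_c": (float, False),
        "rh_nm": (float, True),
    },
    "hsr": {
        "temperature_c": (float, False),
        "response_fold": (float, False),
    },
    "hdx_peptides": {
        "protein": (str, False),
        "state": (str, False),
        "start": (int, True),
        "end": (int, True),
        "sequence": (str, False),
        "timepoint_s": (float, True),
        "mass_t": (float, True),
        "mass_undeut": (float, True),
        "mass_sat": (float, True),
    },
    "psup": {
        "protein_id": (str, False),
        "psup": (float, False),
        "ci_low": (float, False),
        "ci_high": (float, False),
    },
    "foldchange": {
        "gene": (str, False),
        "species": (str, False),
        "log2fc": (float, False),
    },
    "ortholog_map": {
        "id_a": (str, False),
        "id_b": (str, False),
    },
    "class_map": {
        "protein_id": (str, False),
        "protein_class": (str, False),
    },
    "regulon_map": {
        "gene": (str, False),
        "regulator": (str, False),
    },
}


def read_table(path, schema_name: str) -> pd.DataFrame:
    """Read and validate a TSV against a named schema.

    Required columns must be present (extras pass through); non-numeric
    cells and negative values in non-negative columns are rejected with
    1-based line numbers.  Lines starting with '#' are treated as comments.
    """
    if schema_name not in SCHEMAS:
        raise ValueError(f"unknown schema {schema_name!r}; know {sorted(SCHEMAS)}")
    schema = SCHEMAS[schema_name]
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path.name}: schema {schema_name!r} missing columns {missing}"
        )
    for col, (dtype, non_negative) in schema.items():
        if dtype in (float, int):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                line = int(df.index[bad][0]) + 2  # +1 header, +1 1-based
                raise ValueError(
                    f"{path.name}: non-numeric value in column {col!r} "
                    f"at line {line}"
                )
            if non_negative and (coerced < 0).any():
                line = int(df.index[coerced < 0][0]) + 2
                raise ValueError(
                    f"{path.name}: negative value in column {col!r} at line {line}"
                )
            df[col] = coerced.astype(dtype)
        else:
            df[col] = df[col].astype(str)
    return df


def _header_comment(stage: str, config_digest: str = "") -> str:
    from thermosol import __version__

    return (
        f"# thermosol {__version__} | stage: {stage}"
        + (f" | config: {config_digest}" if config_digest else "")
        + "\n"
    )


def write_table(
    df: pd.DataFrame, path, stage: str = "", config_digest: str = ""
) -> None:
    """Write a TSV with a provenance header comment."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header_comment(stage or "table", config_digest))
        df.to_csv(fh, sep="\t", index=False)


def read_fasta(path, strict: bool = True) -> dict[str, str]:
    """FASTA records as an id -> amino-acid-sequence mapping.

    Duplicate ids are rejected; with ``strict=True`` so are non-standard
    residue characters.  An empty file is an error.
    """
    from Bio import SeqIO

    from thermosol.hdx import AMINO_ACIDS

    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seq = str(rec.seq).upper()
        if strict:
            bad = set(seq) - AMINO_ACIDS
            if bad:
                raise ValueError(
                    f"illegal residue characters in {rec.id!r}: {sorted(bad)}"
                )
        records[rec.id] = seq
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(sequences: dict[str, str], path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


# ------------------------------------------------------------- pipeline

KNOWN_STAGES = ("simulate", "psup", "compare")

_KNOWN_KEYS = {
    "stages",
    "seed",
    "n_proteins",
    "alpha_s",
    "alpha_p",
    "sigma",
    "noise_model",
    "intensity_threshold",
    "n_chains",
    "n_warmup",
    "n_draws",
    "log_level",
    "out_dir",
}


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    Every stochastic stage draws from the single explicit ``seed``; unknown
    keys are rejected so typos cannot silently change a run.
    """

    stages: list = field(default_factory=lambda: ["simulate", "psup", "compare"])
    seed: int | None = None
    n_proteins: int = 500
    alpha_s: float = 0.8
    alpha_p: float = 1.2
    sigma: float = 0.1
    noise_model: str = "lognormal"
    intensity_threshold: float = 1.0
    n_chains: int = 4
    n_warmup: int = 500
    n_draws: int = 500
    log_level: str = "INFO"
    out_dir: str = "thermosol_run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if cfg.seed is None:
            raise ValueError("config must set an explicit seed")
        for stage in cfg.stages:
            if stage not in KNOWN_STAGES:
                raise ValueError(f"unknown stage {stage!r}; know {KNOWN_STAGES}")
        return cfg

    def to_dict(self) -> dict:
        return {
            "stages": list(self.stages),
            "seed": self.seed,
            "n_proteins": self.n_proteins,
            "alpha_s": self.alpha_s,
            "alpha_p": self.alpha_p,
            "sigma": self.sigma,
            "noise_model": self.noise_model,
            "intensity_threshold": self.intensity_threshold,
            "n_chains": self.n_chains,
            "n_warmup": self.n_warmup,
            "n_draws": self.n_draws,
            "log_level": self.log_level,
            "out_dir": self.out_dir,
        }

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def run_pipeline(config: RunConfig, out_dir=None) -> Path:
    """Run simulate -> psup -> compare stages from one config.

    Writes every stage output, a run log (stage, parameters, seed, dropped
    records, convergence flags) and the echoed config into the output
    directory.  Reruns with identical config reproduce every stochastic
    output bit for bit.
    """
    from thermosol import crossspecies, psup, simulate

    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    digest = config.digest()
    log: list[dict] = []

    def log_event(stage: str, **info):
        log.append({"time": time.strftime("%Y-%m-%dT%H:%M:%S"), "stage": stage, **info})

    quant_by_cond, truth_by_cond = {}, {}
    if "simulate" in config.stages:
        scenario = simulate.default_scenario(
            config.n_proteins, noise_model=config.noise_model
        )
        for k, condition in enumerate(("basal", "shocked")):
            quant, truth = simulate.simulate_fractionation(
                scenario,
                config.alpha_s,
                config.alpha_p,
                config.sigma,
                seed=config.seed + k,
                condition=condition,
            )
            quant_by_cond[condition] = quant
            truth_by_cond[condition] = truth
            write_table(
                quant, out / f"fractionation_{condition}.tsv", "simulate", digest
            )
            write_table(
                truth.to_frame(), out / f"truth_{condition}.tsv", "simulate", digest
            )
        log_event("simulate", seed=config.seed, n_proteins=config.n_proteins)

    psup_by_cond = {}
    if "psup" in config.stages:
        if not quant_by_cond:
            raise RuntimeError("psup stage requires the simulate stage (or inputs)")
        for condition, quant in quant_by_cond.items():
            model = psup.MixingRatioModel(quant, config.intensity_threshold)
            res = model.fit(
                n_chains=config.n_chains,
                n_warmup=config.n_warmup,
                n_draws=config.n_draws,
                seed=config.seed,
            )
            est = res.compute_psup(quant, force=True)
            psup_by_cond[condition] = est
            write_table(est, out / f"psup_{condition}.tsv", "psup", digest)
            (out / f"mixing_{condition}.json").write_text(
                json.dumps(
                    {
                        "alpha_s": res.alpha_s,
                        "alpha_p": res.alpha_p,
                        "sigma": res.sigma,
                        "rhat": res.rhat,
                        "ess": res.ess,
                        "converged": res.converged,
                        "seed": res.seed,
                        "n_chains": res.n_chains,
                        "n_draws": res.n_draws,
                    },
                    indent=2,
                )
            )
            log_event(
                "psup",
                condition=condition,
                converged=res.converged,
                n_dropped_zero_zero=model.n_dropped_zero_zero,
            )

    if "compare" in config.stages:
        if not psup_by_cond:
            raise RuntimeError("compare stage requires the psup stage")
        classes = {
            f"prot{i:05d}": c
            for i, c in enumerate(truth_by_cond["basal"].protein_class)
        }
        vectors = {}
        for condition, est in psup_by_cond.items():
            summ = class_means = class_summary_frame(est, classes)
            vectors[f"sim_{condition}"] = class_means.set_index("protein_class")[
                "mean"
            ]
            write_table(summ, out / f"class_summary_{condition}.tsv", "compare", digest)
        r2 = crossspecies.condition_correlation_matrix(
            pd.DataFrame(vectors), min_shared=2
        )
        write_table(
            r2.reset_index().rename(columns={"index": "cell"}),
            out / "correlation_matrix.tsv",
            "compare",
            digest,
        )
        log_event("compare", cells=list(vectors))

    (out / "run_log.json").write_text(json.dumps(log, indent=2))
    (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict()))
    return out


def class_summary_frame(est: pd.DataFrame, classes: dict) -> pd.DataFrame:
    from thermosol.crossspecies import class_summary

    return class_summary(est.dropna(subset=["psup"]), classes)
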