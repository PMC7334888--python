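"""Structured run configuration: schema validation and object construction.

A run config is one YAML file mapping 1:1 onto :class:`SimulationConfig`
plus output paths. Validation is strict — unknown keys are rejected with the
dotted path of the offending key — and happens before any simulation starts.
"""

from __future__ import annotations

import yaml

from .germline import (
    FrequencyTable,
    GermlineSet,
    LengthDistribution,
    CHAINS,
    generate_synthetic_germline_set,
    geometric_frequency_table,
    load_germline_fasta,
    perturb_frequency_table,
    read_frequency_table,
    read_length_distribution,
    uniform_frequency_table,
)
from .engine import SimulationConfig
from .shaping import AbundanceModel


class ConfigError(ValueError):
    """Invalid run configuration; ``path`` is the dotted key path."""

    def __init__(self, path: str, message: str):
        self.path = path
        super().__init__(f"config error at '{path}': {message}")


#: key -> allowed sub-keys (None means scalar leaf)
_SCHEMA: dict[str, set[str] | None] = {
    "species": None,
    "chain": None,
    "n_sequences": None,
    "seed": None,
    "max_attempts_per_sequence": None,
    "log_level": None,
    "germline": {"source", "n_v", "n_d", "n_j", "seed", "v_len", "d_len",
                 "j_len", "v_fasta", "d_fasta", "j_fasta"},
    "frequencies": {"mode", "decay", "v_file", "d_file", "j_file",
                    "noise_sd", "noise_seed"},
    "trims": {"v_mean", "d5_mean", "d3_mean", "j_mean", "max_len",
              "v_file", "d5_file", "d3_file", "j_file"},
    "insertions": {"n1_mean", "n2_mean", "max_len", "n1_file", "n2_file"},
    "shm": {"rate_per_site", "hotspot_multiplier"},
    "abundance": {"kind", "alpha", "c_max", "counts"},
    "output": {"tsv", "manifest", "fasta", "fasta_level"},
}

_REQUIRED = ("chain", "n_sequences", "seed", "germline", "output")


def load_run_config(path) -> dict:
    """Load and schema-validate a YAML run config."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("<root>", "config must be a mapping")
    validate_run_config(cfg)
    return cfg


def validate_run_config(cfg: dict) -> None:
    for key in cfg:
        if key not in _SCHEMA:
            raise ConfigError(key, "unknown key")
        allowed = _SCHEMA[key]
        if allowed is None:
            if isinstance(cfg[key], dict):
                raise ConfigError(key, "expected a scalar")
            continue
        if not isinstance(cfg[key], dict):
            raise ConfigError(key, "expected a mapping")
        for sub in cfg[key]:
            if sub not in allowed:
                raise ConfigError(f"{key}.{sub}", "unknown key")
    for key in _REQUIRED:
        if key not in cfg:
            raise ConfigError(key, "required key missing")
    if cfg["chain"] not in CHAINS:
        raise ConfigError("chain", f"must be one of {CHAINS}")
    if not isinstance(cfg["n_sequences"], int) or cfg["n_sequences"] < 1:
        raise ConfigError("n_sequences", "must be a positive integer")
    if not isinstance(cfg["seed"], int):
        raise ConfigError("seed", "must be an integer")
    src = cfg["germline"].get("source", "synthetic")
    if src not in ("synthetic", "fasta"):
        raise ConfigError("germline.source", "must be 'synthetic' or 'fasta'")
    if src == "fasta" and "v_fasta" not in cfg["germline"]:
        raise ConfigError("germline.v_fasta", "required for source=fasta")
    mode = cfg.get("frequencies", {}).get("mode", "uniform")
    if mode not in ("uniform", "geometric", "files"):
        raise ConfigError("frequencies.mode",
                          "must be 'uniform', 'geometric' or 'files'")
    if "tsv" not in cfg["output"]:
        raise ConfigError("output.tsv", "required key missing")


def build_germline(cfg: dict) -> GermlineSet:
    g = cfg["germline"]
    chain = cfg["chain"]
    if g.get("source", "synthetic") == "synthetic":
        kwargs = {}
        for rng_key in ("v_len", "d_len", "j_len"):
            if rng_key in g:
                kwargs[rng_key] = tuple(g[rng_key])
        return generate_synthetic_germline_set(
            n_v=g.get("n_v", 20), n_d=g.get("n_d", 10 if chain in
                                            ("IGH", "TRB") else 0),
            n_j=g.get("n_j", 5), seed=g.get("seed", cfg["seed"]),
            chain=chain, species=cfg.get("species", "synthetic"), **kwargs)
    v_genes, v_rej = load_germline_fasta(g["v_fasta"], "V")
    j_genes, j_rej = load_germline_fasta(g["j_fasta"], "J")
    if v_rej or j_rej:
        raise ConfigError("germline",
                          f"rejected germline records: {v_rej + j_rej}")
    d_genes = []
    if "d_fasta" in g:
        d_genes, _ = load_germline_fasta(g["d_fasta"], "D")
    return GermlineSet(species=cfg.get("species", "user"), chain=chain,
                       v_genes=v_genes, d_genes=d_genes, j_genes=j_genes)


def _build_freq(cfg: dict, germline: GermlineSet,
                segment_class: str) -> FrequencyTable | None:
    genes = germline.genes(segment_class)
    if not genes:
        return None
    f = cfg.get("frequencies", {})
    mode = f.get("mode", "uniform")
    if mode == "files":
        key = f"{segment_class.lower()}_file"
        if key not in f:
            raise ConfigError(f"frequencies.{key}", "required for mode=files")
        table = read_frequency_table(f[key], segment_class)
    elif mode == "geometric":
        table = geometric_frequency_table(genes, f.get("decay", 0.8))
    else:
        table = uniform_frequency_table(genes)
    noise = f.get("noise_sd", 0.0)
    if noise:
        table = perturb_frequency_table(table, noise,
                                        f.get("noise_seed", cfg["seed"]))
    return table


def _build_dist(stanza: dict, file_key: str, mean_key: str, default_mean: float,
                purpose: str, max_len: int) -> LengthDistribution:
    if file_key in stanza:
        return read_length_distribution(stanza[file_key], purpose)
    return LengthDistribution.geometric(stanza.get(mean_key, default_mean),
                                        purpose, max_len)


def build_simulation_config(cfg: dict,
                            germline: GermlineSet | None = None
                            ) -> SimulationConfig:
    if germline is None:
        germline = build_germline(cfg)
    trims = cfg.get("trims", {})
    ins = cfg.get("insertions", {})
    t_max = trims.get("max_len", 15)
    i_max = ins.get("max_len", 15)
    shm = cfg.get("shm", {})
    ab = cfg.get("abundance", {})
    model = None
    if ab:
        model = AbundanceModel(
            kind=ab.get("kind", "uniform"), alpha=ab.get("alpha"),
            c_max=ab.get("c_max", 10_000),
            empirical_counts=tuple(ab["counts"]) if "counts" in ab else None)
    sim = SimulationConfig(
        germline_set=germline,
        v_freq=_build_freq(cfg, germline, "V"),
        d_freq=_build_freq(cfg, germline, "D"),
        j_freq=_build_freq(cfg, germline, "J"),
        n_sequences=cfg["n_sequences"],
        seed=cfg["seed"],
        v_trim_dist=_build_dist(trims, "v_file", "v_mean", 2.0, "v_trim", t_max),
        d_trim5_dist=(_build_dist(trims, "d5_file", "d5_mean", 2.0,
                                  "d_trim_5", t_max)
                      if germline.has_d else None),
        d_trim3_dist=(_build_dist(trims, "d3_file", "d3_mean", 2.0,
                                  "d_trim_3", t_max)
                      if germline.has_d else None),
        j_trim_dist=_build_dist(trims, "j_file", "j_mean", 2.0, "j_trim", t_max),
        n1_dist=_build_dist(ins, "n1_file", "n1_mean", 4.0, "n1_len", i_max),
        n2_dist=(_build_dist(ins, "n2_file", "n2_mean", 4.0, "n2_len", i_max)
                 if germline.has_d else None),
        shm_rate=shm.get("rate_per_site", 0.0),
        shm_hotspot_multiplier=shm.get("hotspot_multiplier", 1.0),
        abundance_model=model,
        species=cfg.get("species"),
        max_attempts_per_sequence=cfg.get("max_attempts_per_sequence", 1000),
    )
    sim.validate()
    return sim
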