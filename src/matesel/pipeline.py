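"""End-to-end run: parentage audit -> hypothesis suite -> GLMM, with figures.

Driven by a YAML config (see ``example_config`` below).  Data either come
from input files (adults TSV, pairs TSV, trios TSV, allele FASTA) or from
the built-in generator (``simulate:`` section).  All outputs are TSV plus a
JSON manifest; figures show each null distribution as a histogram with the
observed value (solid line) and the two-tailed 95 percent CI cutoffs
(dashed lines), and the reproductive-success model as class effects with a
bootstrap band.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import yaml

from . import glmm, io, parentage, randomization, simulate
from .types import Dataset

__all__ = ["run_full_pipeline", "example_config", "plot_null_distribution"]


def example_config() -> dict:
    return {
        "seed": 42,
        "n_iter": 9999,
        "simulate": {"preference": "heterozygote", "beta": 2.0},
        "d2_unit": "repeats",
        "aa_model": "p",
        "glmm": {"locus": None, "n_boot": 1000},
    }


def plot_null_distribution(
    result: randomization.RandomizationResult, path: Path
) -> None:
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.hist(result.null, bins=40, color="0.7", edgecolor="0.5")
    ax.axvline(result.observed, color="black", lw=2, label="observed")
    ax.axvline(result.ci_low, color="black", ls="--", lw=1)
    ax.axvline(result.ci_high, color="black", ls="--", lw=1, label="95% CI")
    ax.set_xlabel(result.statistic)
    ax.set_ylabel("frequency")
    ax.set_title(f"{result.statistic}: p = {result.p:.4g}")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _load_inputs(cfg: dict):
    inputs = cfg["inputs"]
    dataset = io.read_individuals(inputs["individuals"])
    pairs = io.read_pairs(inputs["pairs"], dataset)
    catalogue = io.read_allele_fasta(inputs["alleles"])
    trios = io.read_trios(inputs["trios"]) if inputs.get("trios") else []
    return dataset, catalogue, pairs, trios, None


def _simulate_inputs(cfg: dict):
    sim_cfg = dict(cfg.get("simulate") or {})
    sim_cfg.setdefault("seed", cfg.get("seed", 0))
    config = simulate.GeneratorConfig(**sim_cfg)
    data = simulate.generate_dataset(config)
    return data.dataset, data.catalogue, data.pairs, data.trios, data.truth


def run_full_pipeline(config: dict | str | Path, out_dir: str | Path) -> Path:
    """Run every stage and write results under ``out_dir``.

    Deterministic given config + seed.  Returns the output directory.
    Raises before any computation if the config is malformed.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    known = {"seed", "n_iter", "simulate", "inputs", "d2_unit", "aa_model",
             "glmm", "figures", "max_mismatch"}
    unknown = set(config) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "inputs" not in config and "simulate" not in config:
        raise ValueError("config needs an 'inputs' or a 'simulate' section")
    seed = int(config.get("seed", 0))
    n_iter = int(config.get("n_iter", 9999))

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if "inputs" in config:
        dataset, catalogue, pairs, trios, truth = _load_inputs(config)
    else:
        dataset, catalogue, pairs, trios, truth = _simulate_inputs(config)
        io.write_individuals(dataset, out / "adults.tsv")
        io.write_pairs(pairs, out / "pairs.tsv")
        io.write_allele_fasta(catalogue, out / "alleles.fasta")
        if trios:
            io.write_trios(trios, out / "trios.tsv")
        (out / "truth.json").write_text(json.dumps(truth, indent=2, default=str))

    # stage 1: Mendelian parentage audit
    if trios:
        audit = parentage.audit_dataset(trios, max_mismatch=int(config.get("max_mismatch", 0)))
        audit.to_csv(out / "parentage_audit.tsv", sep="\t", index=False)

    # stage 2: hypothesis suite (stratified randomisation tests)
    table, results = randomization.run_hypothesis_suite(
        dataset, pairs, catalogue,
        n_iter=n_iter, seed=seed,
        d2_unit=config.get("d2_unit", "repeats"),
        aa_model=config.get("aa_model", "p"),
    )
    table.to_csv(out / "hypothesis_tests.tsv", sep="\t", index=False)
    if config.get("figures", True):
        fig_dir = out / "figures"
        fig_dir.mkdir(exist_ok=True)
        for name, result in results.items():
            plot_null_distribution(result, fig_dir / f"null_{name}.png")

    # stage 3: reproductive success GLMM
    glmm_cfg = dict(config.get("glmm") or {})
    locus = glmm_cfg.get("locus") or dataset.mhc_loci[0]
    clutches = simulate.clutches_frame(pairs, dataset, locus)
    glmm_out: dict[str, object] = {"locus": locus}
    try:
        fit = glmm.fit_poisson_random_intercept(clutches)
        glmm_out.update(
            beta0=fit.beta0, beta_zyg=fit.beta_zyg, sigma_u=fit.sigma_u,
            se_beta_zyg=fit.se_beta_zyg, wald_p=fit.wald_p,
            n_clutches=fit.n_clutches, n_males=fit.n_males,
            converged=fit.converged,
        )
        n_boot = int(glmm_cfg.get("n_boot", 0))
        if n_boot:
            band = glmm.bootstrap_effect_ci(clutches, n_boot=n_boot, seed=seed)
            band.to_csv(out / "glmm_bootstrap_band.tsv", sep="\t", index=False)
            if config.get("figures", True):
                _plot_glmm(band, out / "figures" / "glmm_effect.png")
    except ValueError as exc:
        glmm_out["error"] = str(exc)
    (out / "glmm.json").write_text(json.dumps(glmm_out, indent=2, default=str))

    cfg_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()
    io.write_manifest(
        out / "manifest.json",
        config=config, config_sha256=cfg_hash, seed=seed, n_iter=n_iter,
        n_individuals=len(dataset), n_pairs=len(pairs), n_trios=len(trios),
    )
    return out


def _plot_glmm(band, path: Path) -> None:
    path.parent.mkdir(exist_ok=True)
    fig, ax = plt.subplots(figsize=(4, 3.5))
    x = band["zygosity"]
    ax.errorbar(
        x, band["predicted"],
        yerr=[band["predicted"] - band["ci_low"], band["ci_high"] - band["predicted"]],
        fmt="o", capsize=4, color="black",
    )
    ax.set_xticks([0, 1])
    ax.set_xticklabels(["homozygote", "heterozygote"])
    ax.set_ylabel("predicted clutch size")
    ax.set_xlim(-0.5, 1.5)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
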