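"""End-to-end pipelines: corpus -> cochleogram -> network -> analyses, plus
the control-experiment variant suite (no pooling, average pooling, L2
regularizer, larger-kernel top layer).

Two profiles are provided: ``test`` (4-layer net, small map counts, ~200
token corpus, minutes on one CPU) and ``full`` (the 12-layer architecture at
the published map counts).  Every stochastic stage is seeded; reruns with
the same config produce byte-identical artifacts and manifest hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import corpus as corpus_mod
from . import decoding as dec
from . import dynamics as dyn
from . import selectivity as sel
from .cochlea import build_filterbank, cochleogram, write_wav
from .model import (SHMAX, ArchitectureSpec, default_architecture, rf_extent,
                    compact_architecture)

log = logging.getLogger("shmax")

__all__ = ["RunConfig", "make_corpus", "run_pipeline", "variant_suite"]


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    profile: str = "test"  # test | full
    seed: int = 0
    n_phonemes: int = 33
    n_tokens: int = 200
    jitter_sd: float = 0.05
    n_channels: int = 194
    f_lo: float = 73.0
    f_hi: float = 7630.0
    n_patches: int = 2000
    epochs: int = 3
    pool_mode: str = "max"
    regularizer: str = "L1"
    lam: float = 1.0
    analysis_layer: str | None = None  # default: top layer of the profile
    n_groups: int = 6
    folds: int = 20
    run_psi: bool = True
    run_decode: bool = True
    run_tvi: bool = True
    run_sweep: bool = False
    sweep_lambdas: tuple[float, ...] = (0.001, 0.01, 0.1, 1.0, 3.0, 10.0)
    out_dir: str = "shmax_run"

    def architecture(self) -> ArchitectureSpec:
        if self.profile == "full":
            return default_architecture(pool_mode=self.pool_mode, lam=self.lam,
                                        regularizer=self.regularizer)
        if self.profile == "test":
            return compact_architecture(pool_mode=self.pool_mode, lam=self.lam,
                                     regularizer=self.regularizer)
        raise ValueError(f"unknown profile {self.profile!r}")

    @property
    def top_layer(self) -> str:
        return self.analysis_layer or self.architecture().names[-1]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "sweep_lambdas" in data:
            data["sweep_lambdas"] = tuple(data["sweep_lambdas"])
        return cls(**data)


def make_corpus(cfg: RunConfig):
    """Generate the synthetic corpus and its cochleogram for a config."""
    inventory = corpus_mod.make_inventory(cfg.n_phonemes, seed=cfg.seed)
    wav, transcript, truth = corpus_mod.synthesize(
        inventory, cfg.n_tokens, jitter_sd=cfg.jitter_sd, seed=cfg.seed + 1
    )
    fb = build_filterbank(cfg.n_channels, cfg.f_lo, cfg.f_hi, corpus_mod.SAMPLE_RATE)
    cg = cochleogram(wav, fb)
    return inventory, wav, transcript, truth, cg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _train(cfg: RunConfig, cg):
    arch = cfg.architecture()
    t0 = time.time()
    results = SHMAX([cg], arch).fit(n_patches=cfg.n_patches, epochs=cfg.epochs,
                                    seed=cfg.seed + 2)
    log.info("trained %s profile in %.1f s (seed %d)", cfg.profile,
             time.time() - t0, cfg.seed)
    return results


def _analyses(cfg: RunConfig, inventory, transcript, truth, cg, results, out: Path):
    layer = cfg.top_layer
    artifacts: dict[str, pd.DataFrame | str] = {}

    table = sel.response_amplitudes(results, transcript, layer, seed=cfg.seed)
    act = sel.active_units(table)
    if len(act) <= cfg.n_groups:
        act = np.arange(table.n_units)  # fall back to all units
    psi = sel.psi_matrix(table, act)
    psi = sel.cluster_psi(psi, n_groups=min(cfg.n_groups, max(2, len(act) - 1)))
    fr = sel.f_ratio(psi)

    if cfg.run_psi:
        psi_df = pd.DataFrame(psi.values, columns=psi.phoneme_labels)
        psi_df.insert(0, "unit", psi.unit_ids)
        psi_df.insert(1, "group", psi.groups)
        psi_df.to_csv(out / "psi.tsv", sep="\t", index=False)
        fmap = sel.phoneme_feature_map(inventory)
        sel.feature_psi(psi, fmap).to_csv(out / "feature_psi.tsv", sep="\t")
        (out / "f_ratio.txt").write_text(f"{layer}\t{fr}\n")
        artifacts["f_ratio"] = fr

    if cfg.run_decode:
        params = dec.estimate_params(cg, transcript, truth)
        X, meta = dec.amplitude_matrix(results, transcript, layer)
        rows = []
        group_rows = []
        unit_groups = np.zeros(X.shape[1], dtype=int)
        unit_groups[psi.unit_ids] = psi.groups
        for pname in ("f0", "f1", "f2", "vot", "spectral_peak"):
            y = params[pname].to_numpy(dtype=float)
            if np.isfinite(y).sum() < cfg.folds:
                continue
            res = dec.decode_with_significance(X, y, folds=cfg.folds, seed=cfg.seed,
                                               parameter=pname)
            rows.append({"parameter": pname, "layer": layer,
                         "mean_accuracy": res.mean_accuracy,
                         "random_accuracy": float(np.mean(res.random_accuracies)),
                         "p_value": res.p_value})
            gdf = dec.group_decoding(X, unit_groups, y, folds=cfg.folds,
                                     seed=cfg.seed, parameter=pname)
            gdf.insert(0, "layer", layer)
            group_rows.append(gdf)
        decode_df = pd.DataFrame(rows)
        decode_df.to_csv(out / "decode.tsv", sep="\t", index=False)
        if group_rows:
            pd.concat(group_rows).to_csv(out / "group_decode.tsv", sep="\t",
                                         index=False)
        artifacts["decode"] = decode_df

    if cfg.run_tvi:
        contours = dyn.build_contours(truth, transcript)
        resp_by_phoneme = _mean_response_per_phoneme(results, transcript, layer,
                                                     contours.labels)
        rows = []
        for formant in ("F1", "F2"):
            tvis, _ = dyn.tvi(contours, formant)
            corr = dyn.tvi_correlation(resp_by_phoneme, tvis)
            for u, c in enumerate(corr):
                rows.append({"unit": u, "formant": formant, "correlation": c})
        tvi_df = pd.DataFrame(rows)
        tvi_df.to_csv(out / "tvi.tsv", sep="\t", index=False)
        artifacts["tvi"] = tvi_df

    if cfg.run_sweep:
        sweep = sel.lambda_sweep([cg], transcript, cfg.architecture(), layer,
                                 cfg.sweep_lambdas, seed=cfg.seed,
                                 n_patches=cfg.n_patches, epochs=cfg.epochs,
                                 n_groups=min(cfg.n_groups, 4))
        sweep.to_csv(out / "sweep.tsv", sep="\t", index=False)
        artifacts["sweep"] = sweep
    return artifacts


def _mean_response_per_phoneme(results, transcript, layer, labels):
    X, meta = dec.amplitude_matrix(results, transcript, layer)
    out = []
    for lab in labels:
        rows = meta.index[meta["label"] == lab]
        out.append(X[rows].mean(axis=0))
    return np.stack(out, axis=1)  # (units, P)


def run_pipeline(cfg: RunConfig) -> Path:
    """Run corpus generation, the front-end, training and the enabled
    analyses; write all artifacts plus a content-hash manifest.

    Returns the run directory.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)

    inventory, wav, transcript, truth, cg = make_corpus(cfg)
    write_wav(out / "corpus.wav", wav)
    corpus_mod.write_phn(out / "corpus.phn", transcript)
    corpus_mod.write_ground_truth(out / "ground_truth.tsv", truth)

    results = _train(cfg, cg)
    results.save(out / "model.h5")
    (out / "summary.txt").write_text(results.summary() + "\n")
    _analyses(cfg, inventory, transcript, truth, cg, results, out)

    manifest = {
        "config": asdict(cfg),
        "files": {p.name: _sha256(p) for p in sorted(out.iterdir())
                  if p.is_file() and p.name != "manifest.json"},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out


def _model_hash(results) -> str:
    h = hashlib.sha256()
    for name in sorted(results.banks):
        h.update(results.banks[name].bases.tobytes())
    return h.hexdigest()


def variant_suite(cfg: RunConfig, variants=("max", "average", "none", "L2", "kernel20")
                  ) -> pd.DataFrame:
    """Train the pooling/regularizer/kernel control variants on the same
    corpus and seed; report layer F-ratio, decoding accuracy for F1, and a
    model content hash per variant."""
    inventory, wav, transcript, truth, cg = make_corpus(cfg)
    params = dec.estimate_params(cg, transcript, truth)
    rows = []
    for variant in variants:
        vcfg = replace(cfg, run_sweep=False)
        if variant in ("max", "average", "none"):
            vcfg = replace(vcfg, pool_mode=variant)
            arch = vcfg.architecture()
        elif variant == "L2":
            vcfg = replace(vcfg, regularizer="L2")
            arch = vcfg.architecture()
        elif variant == "kernel20":
            arch = vcfg.architecture()
            layers = list(arch.layers)
            # double the kernel of the last S layer (receptive-field control)
            for i in range(len(layers) - 1, -1, -1):
                if layers[i].kind == "S":
                    layers[i] = replace(layers[i], kernel=layers[i].kernel * 2)
                    break
            arch = ArchitectureSpec(tuple(layers))
        else:
            raise ValueError(f"unknown variant {variant!r}")
        results = SHMAX([cg], arch).fit(n_patches=vcfg.n_patches, epochs=vcfg.epochs,
                                        seed=vcfg.seed + 2)
        layer = arch.names[-1]
        table = sel.response_amplitudes(results, transcript, layer, seed=vcfg.seed)
        try:
            act = sel.active_units(table)
        except ValueError:
            act = np.arange(table.n_units)
        if len(act) <= 2:
            act = np.arange(table.n_units)
        psi = sel.cluster_psi(sel.psi_matrix(table, act),
                              n_groups=min(vcfg.n_groups, max(2, len(act) - 1)))
        fr = sel.f_ratio(psi)
        X, _ = dec.amplitude_matrix(results, transcript, layer)
        y = params["f1"].to_numpy(dtype=float)
        try:
            res = dec.decode_with_significance(X, y, folds=vcfg.folds, seed=vcfg.seed,
                                               parameter="f1")
            acc, pval = res.mean_accuracy, res.p_value
        except ValueError:
            acc, pval = np.nan, np.nan
        rows.append({"variant": variant, "layer": layer,
                     "rf_frames": rf_extent(arch, layer)[1],
                     "n_active": len(act), "f_ratio": fr,
                     "f1_accuracy": acc, "f1_p": pval,
                     "model_hash": _model_hash(results)})
    return pd.DataFrame(rows)
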