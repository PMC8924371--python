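"""End-to-end orchestration: simulate -> score -> fit -> report.

`run_demo` reproduces the logic of a pH-stress viability screen on
synthetic data: a three-condition screen is simulated, both acid contrasts
(6.63 vs 7.4 and 6.9 vs 7.4) are scored, hits are called at FDR 0.1 and
intersected, planted-class overrepresentation is computed, wild-type and
acid-shifted "knockout" growth plates are fitted for pH50, and everything
is written to an output directory with a provenance record. Re-running
with the same config and seed reproduces every output byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, acidfit, screenz, simdata

log = logging.getLogger("acidscreen")

ACID_PH = 6.63
MILD_PH = 6.9
PHYS_PH = 7.4


@dataclass
class RunConfig:
    n_genes: int = 2000
    guides_per_gene: int = 4
    depth: float = 500.0
    n_replicates: int = 2
    fdr: float = 0.1
    n_boot: int = 200
    ko_acid_shift: float = 0.3   # pK_inh shift of the demo knockout curve
    plate_noise_cv: float = 0.05
    seed: int = 0
    outdir: str = "acidscreen_demo"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        # outdir is a location, not an analysis parameter
        params = {k: v for k, v in asdict(self).items() if k != "outdir"}
        blob = json.dumps(params, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class StageError(RuntimeError):
    stage: str
    message: str

    def __str__(self) -> str:
        return f"[{self.stage}] {self.message}"


def _provenance(cfg: RunConfig, inputs: dict[str, Path]) -> dict:
    digests = {}
    for name, p in inputs.items():
        digests[name] = hashlib.sha256(Path(p).read_bytes()).hexdigest()[:16]
    return {"tool": "acidscreen", "version": __version__,
            "seed": cfg.seed, "config_sha256": cfg.digest(),
            "input_digests": digests}


def demo_plate_params() -> dict[str, acidfit.BiphasicParams]:
    """Wild-type and acid-sensitized knockout growth curves for the demo."""
    wt = acidfit.BiphasicParams.from_pk(g_max=1.0, pk_act=7.9, n_act=1.2,
                                        pk_inh=6.6, n_inh=1.5)
    return {"WT": wt}


def run_demo(cfg: RunConfig) -> dict:
    """Run the full synthetic demonstration; returns the summary dict."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def stage(name):
        log.info("stage: %s", name)
        return name

    # --- simulate the screen -------------------------------------------
    name = stage("simulate-screen")
    try:
        sim_cfg = simdata.ScreenSimConfig(
            n_genes=cfg.n_genes, guides_per_gene=cfg.guides_per_gene,
            depth=cfg.depth, n_replicates=cfg.n_replicates, seed=cfg.seed)
        matrix, truth = simdata.simulate_screen(sim_cfg)
        counts_path = outdir / "counts.tsv"
        screenz.write_counts(matrix, counts_path)
        truth_path = outdir / "truth.csv"
        truth.to_csv(truth_path)
        written["counts"] = counts_path
        written["truth"] = truth_path
    except Exception as e:  # noqa: BLE001 - stage-tagged abort
        raise StageError(name, str(e)) from e

    # --- score both acid contrasts -------------------------------------
    name = stage("score")
    try:
        scores = {}
        for label, ph in (("6.63_vs_7.4", ACID_PH), ("6.9_vs_7.4", MILD_PH)):
            sc = screenz.score_contrast(matrix, treated_ph=ph,
                                        control_ph=PHYS_PH)
            path = outdir / f"gene_scores_{label}.tsv"
            sc.to_csv(path, sep="\t", float_format="%.6g")
            written[f"scores_{label}"] = path
            scores[label] = sc
    except Exception as e:
        raise StageError(name, str(e)) from e

    # --- hits, overlap, overrepresentation -----------------------------
    name = stage("hits")
    try:
        hits = {}
        for label, sc in scores.items():
            for direction in ("depleted", "enriched"):
                hs = screenz.call_hits(sc, direction, cfg.fdr)
                hits[(label, direction)] = hs
                path = outdir / f"hits_{label}_{direction}.tsv"
                pd.Series(sorted(hs.genes), name="gene").to_csv(
                    path, sep="\t", index=False)
                written[f"hits_{label}_{direction}"] = path
        venn = {}
        for direction in ("depleted", "enriched"):
            (na, nb_both, nb), _ = screenz.set_overlap(
                hits[("6.9_vs_7.4", direction)],
                hits[("6.63_vs_7.4", direction)])
            venn[direction] = {"only_6.9": na, "both": nb_both,
                               "only_6.63": nb}
        class_sets = {f"class:{c}": set(truth.index[truth["class_label"] == c])
                      for c in simdata.CLASSES}
        enr = screenz.overrepresentation(
            hits[("6.63_vs_7.4", "depleted")].genes, class_sets,
            set(truth.index))
        enr_path = outdir / "overrepresentation_6.63_depleted.tsv"
        enr.to_csv(enr_path, sep="\t", float_format="%.6g")
        written["overrepresentation"] = enr_path
    except Exception as e:
        raise StageError(name, str(e)) from e

    # --- growth plates and pH50 ----------------------------------------
    name = stage("fit-growth")
    try:
        wt = demo_plate_params()["WT"]
        ko = acidfit.BiphasicParams.from_pk(
            g_max=wt.g_max, pk_act=wt.pk_act, n_act=wt.n_act,
            pk_inh=wt.pk_inh + cfg.ko_acid_shift, n_inh=wt.n_inh)
        plate = simdata.simulate_growth_plate(
            {"WT": wt, "KO": ko}, simdata.bicarb_ph_levels(),
            n_reps=3, noise_cv=cfg.plate_noise_cv, seed=cfg.seed)
        plate_path = outdir / "plate.csv"
        plate.to_csv(plate_path, index=False, float_format="%.6g")
        written["plate"] = plate_path
        fits = acidfit.fit_plate(plate)
        cmp_ = acidfit.compare_pH50(
            fits["WT"], fits["KO"],
            plate[plate["group"] == "WT"], plate[plate["group"] == "KO"],
            n_boot=cfg.n_boot, seed=cfg.seed)
        fit_json = {
            g: {"g_max": f.params.g_max, "pK_act": f.params.pk_act,
                "n_act": f.params.n_act, "pK_inh": f.params.pk_inh,
                "n_inh": f.params.n_inh, "pH_opt": f.pH_opt,
                "pH50": f.pH50, "censored": f.censored, "rss": f.rss}
            for g, f in sorted(fits.items())}
        fits_path = outdir / "growth_fits.json"
        fits_path.write_text(json.dumps(fit_json, indent=2, sort_keys=True))
        written["growth_fits"] = fits_path
    except Exception as e:
        raise StageError(name, str(e)) from e

    # --- summary + provenance ------------------------------------------
    name = stage("report")
    try:
        planted = set(truth.index[truth["class_label"] == "acid_essential"])
        depleted = hits[("6.63_vs_7.4", "depleted")]
        recall = (len(depleted.genes & planted) / len(planted)
                  if planted else float("nan"))
        summary = {
            "seed": cfg.seed,
            "n_genes": cfg.n_genes,
            "hits": {f"{label}_{direction}": len(hs)
                     for (label, direction), hs in sorted(hits.items())},
            "boundary_normZ_6.63_depleted": depleted.boundary_normZ,
            "venn": venn,
            "acid_essential_recall_6.63": recall,
            "pH50": {g: fit_json[g]["pH50"] for g in fit_json},
            "delta_pH50_KO_minus_WT": cmp_.delta,
            "delta_pH50_ci": [cmp_.ci_low, cmp_.ci_high],
        }
        summary_path = outdir / "summary.json"
        summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True))
        prov = _provenance(cfg, written)
        (outdir / "provenance.json").write_text(
            json.dumps(prov, indent=2, sort_keys=True))
    except Exception as e:
        raise StageError(name, str(e)) from e
    return summary


def verify_roundtrips(outdir) -> None:
    """Check that every demo writer's output reloads identically."""
    outdir = Path(outdir)
    m = screenz.read_counts(outdir / "counts.tsv")
    tmp = outdir / "_rt_counts.tsv"
    screenz.write_counts(m, tmp)
    if tmp.read_bytes() != (outdir / "counts.tsv").read_bytes():
        raise StageError("roundtrip", "count TSV did not round-trip")
    tmp.unlink()
    plate = pd.read_csv(outdir / "plate.csv")
    tmp = outdir / "_rt_plate.csv"
    plate.to_csv(tmp, index=False, float_format="%.6g")
    if tmp.read_bytes() != (outdir / "plate.csv").read_bytes():
        raise StageError("roundtrip", "plate CSV did not round-trip")
    tmp.unlink()


def setup_logging(verbosity: int = 0) -> None:
    level = logging.WARNING - 10 * min(verbosity, 2)
    logging.basicConfig(stream=sys.stderr, level=level,
                        format="%(levelname)s %(name)s: %(message)s")
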