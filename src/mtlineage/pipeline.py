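"""End-to-end orchestration: load, merge, classify, summarise, embed, date.

The pipeline composes the library modules into the standard analysis of a
control-region reference dataset: haplogroup frequency table, forensic
diversity table, pairwise ΦST matrix with AMOVA and classical MDS, the
haplogroup-P HVS category layer, and — when complete mitogenomes are
supplied — a maximum-parsimony tree with ρ/σ and ML divergences
converted to ages.  Every output is a TSV whose header records the
package version, the seed and a hash of the configuration, so a run is
reproducible byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .codec import (
    DEFAULT_POLICY,
    FRAMES,
    Haplotype,
    HotspotPolicy,
    ReadingFrame,
    read_haplotype_table,
    trim_to_frame,
)
from .dating import ClockModel, convert_to_years, ml_divergence
from .diversity import PopulationSample, diversity_table
from .genealogy import SearchConfig, build_mp_tree, rho_sigma
from .haplogroups import (
    MotifRule,
    classify_P_category,
    haplogroup_frequency_table,
    load_rules,
)
from .reference import ReferenceGenome, read_fasta, synthetic_rcrs
from .structure import amova_two_level, classical_mds, pairwise_fst_matrix


@dataclass
class RunConfig:
    seed: int
    haplotype_table: str | None = None
    frame: str = "hvs1_2"  # preset name or explicit "a-b;c-d" ranges
    policy: HotspotPolicy = field(default_factory=lambda: DEFAULT_POLICY)
    rules_file: str | None = None
    mitogenome_fasta: str | None = None
    root_id: str | None = None  # sequence id of the ancestral haplotype
    clock_rate: float = 2824.0  # years per whole-molecule substitution
    n_permutations: int = 10000
    p_rule_label: str = "P"
    p1d1_motif: str | None = None  # HVS-I motif tokens for P1d1
    out_dir: str = "mtlineage_out"

    def reading_frame(self) -> ReadingFrame:
        return FRAMES.get(self.frame) or ReadingFrame.parse(self.frame)

    def config_hash(self) -> str:
        relevant = {
            k: v
            for k, v in vars(self).items()
            if k != "out_dir" and not isinstance(v, HotspotPolicy)
        }
        blob = json.dumps(relevant, sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


def merge_populations(datasets: list[PopulationSample]) -> list[PopulationSample]:
    """Concatenate samples of identical origin (population name) across
    datasets; duplicate sample ids across sources are rejected so no
    individual is represented twice."""
    by_origin: dict[str, list] = {}
    for ds in datasets:
        by_origin.setdefault(ds.name, []).append(ds)
    merged = []
    for origin, parts in by_origin.items():
        haps = [h for ds in parts for h in ds.haplotypes]
        ids = [h.sample_id for h in haps]
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        if dupes:
            raise ValueError(
                f"duplicate sample ids in origin {origin!r}: {', '.join(dupes)}"
            )
        merged.append(PopulationSample(origin, haps, parts[0].frame, parts[0].policy))
    return merged


def _write(df: pd.DataFrame, path: Path, stamp: str, **kwargs) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {stamp}\n")
        df.to_csv(fh, sep="\t", **kwargs)


def run_pipeline(
    cfg: RunConfig,
    populations: list[PopulationSample] | None = None,
    reference: ReferenceGenome | None = None,
    rules: list[MotifRule] | None = None,
) -> dict:
    """Run the full analysis; returns a dict of result objects and writes
    the TSV report bundle to cfg.out_dir."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = f"mtlineage {__version__} seed={cfg.seed} config={cfg.config_hash()}"
    frame = cfg.reading_frame()
    reference = reference or synthetic_rcrs()
    results: dict = {"config_hash": cfg.config_hash()}

    # ---- load & merge -----------------------------------------------------
    if populations is None:
        if cfg.haplotype_table is None:
            raise ValueError("either populations or a haplotype table is required")
        haps = read_haplotype_table(cfg.haplotype_table)
        by_pop: dict[str, list[Haplotype]] = {}
        for h in haps:
            by_pop.setdefault(h.population or "sample", []).append(h)
        populations = [
            PopulationSample(name, hs, hs[0].frame, cfg.policy)
            for name, hs in by_pop.items()
        ]
    populations = merge_populations(populations)
    populations = [
        PopulationSample(
            p.name, [trim_to_frame(h, frame) for h in p.haplotypes],
            p.haplotypes[0].frame.intersect(frame), cfg.policy
        )
        for p in populations
    ]
    results["populations"] = populations

    # ---- haplogroup classification ---------------------------------------
    if rules is None and cfg.rules_file:
        rules = load_rules(cfg.rules_file)
    if rules:
        freq = haplogroup_frequency_table(populations, rules)
        _write(freq, out / "haplogroup_frequencies.tsv", stamp, index=False)
        results["haplogroup_frequencies"] = freq

        p_rule = next((r for r in rules if r.haplogroup == cfg.p_rule_label), None)
        if p_rule is not None and cfg.p1d1_motif:
            from .codec import parse_haplotype

            motif = frozenset(
                parse_haplotype(cfg.p1d1_motif, ReadingFrame(((1, 16569),))).variants
            )
            rows = []
            for p in populations:
                cats: dict[str, int] = {}
                for h in p.haplotypes:
                    cat = classify_P_category(h, motif, p_rule)
                    cats[cat] = cats.get(cat, 0) + 1
                for cat, n in sorted(cats.items()):
                    rows.append({"Population": p.name, "Category": cat,
                                 "n": n, "pct": round(100 * n / p.n, 1)})
            pcat = pd.DataFrame(rows)
            _write(pcat, out / "p_categories.tsv", stamp, index=False)
            results["p_categories"] = pcat

    # ---- diversity --------------------------------------------------------
    div = diversity_table(populations)
    _write(div, out / "diversity.tsv", stamp, index=False)
    results["diversity"] = div

    # ---- structure --------------------------------------------------------
    if len(populations) >= 2 and all(p.n >= 2 for p in populations):
        fst = pairwise_fst_matrix(populations)
        _write(fst.to_frame(), out / "fst_matrix.tsv", stamp, index_label="")
        amova = amova_two_level(populations, n_permutations=cfg.n_permutations,
                                seed=cfg.seed)
        amova_df = pd.DataFrame([{
            "sigma2_among": amova.sigma2_among,
            "sigma2_within": amova.sigma2_within,
            "phi_st": amova.phi_st,
            "pct_among": amova.pct_among,
            "pct_within": amova.pct_within,
            "p_value": amova.p_value,
            "n_permutations": amova.n_permutations,
        }])
        _write(amova_df, out / "amova.tsv", stamp, index=False)
        mds = classical_mds(fst, k=min(2, len(populations) - 1))
        _write(mds.to_frame(), out / "mds.tsv", stamp, index_label="Population")
        results.update({"fst": fst, "amova": amova, "mds": mds})

    # ---- dating -----------------------------------------------------------
    if cfg.mitogenome_fasta:
        seqs = read_fasta(cfg.mitogenome_fasta)
        if cfg.root_id is None or cfg.root_id not in seqs:
            raise ValueError("root_id must name a sequence in the mitogenome FASTA")
        from .codec import sequence_to_variants

        full = ReadingFrame(((1, len(reference)),))
        root_hap = sequence_to_variants(seqs[cfg.root_id], reference, full,
                                        sample_id=cfg.root_id)
        leaf_haps = [
            sequence_to_variants(s, reference, full, sample_id=name)
            for name, s in seqs.items()
            if name != cfg.root_id
        ]
        trees = build_mp_tree(leaf_haps, root_hap,
                              SearchConfig(seed=cfg.seed))
        tree = trees[0]
        (out / "mp_tree.nwk").write_text(f"[{stamp}]\n" + tree.newick() + "\n")
        (out / "mp_tree.txt").write_text(f"# {stamp}\n" + tree.indented_text() + "\n")
        rho = rho_sigma(tree)
        clock = ClockModel(kind="linear", rate=cfg.clock_rate)
        ml = ml_divergence(tree, seqs)["root"]
        age_rho = convert_to_years(rho.rho, rho.sigma, clock)
        age_ml = convert_to_years(ml.ml_divergence, ml.se, clock)
        table4 = pd.DataFrame([{
            "clade": "root", "n": rho.n,
            "ML": round(ml.ml_divergence, 1), "SE": round(ml.se, 1),
            "T_ml_ky": round(age_ml.T, 1), "dT_ml_ky": round(age_ml.dT, 1),
            "rho": round(rho.rho, 1), "sigma": round(rho.sigma, 1),
            "T_rho_ky": round(age_rho.T, 1), "dT_rho_ky": round(age_rho.dT, 1),
        }])
        _write(table4, out / "dating.tsv", stamp, index=False)
        results.update({"tree": tree, "rho": rho, "ml": ml, "dating": table4})

    # ---- run log ----------------------------------------------------------
    log = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "n_populations": len(populations),
        "frame": str(frame),
        "outputs": sorted({p.name for p in out.iterdir()} | {"run_log.json"}),
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
    results["run_log"] = log
    return results
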