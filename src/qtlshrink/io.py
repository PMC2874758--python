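"""Plain-TSV file formats and run configuration.

Three tab-separated tables describe a dataset (schemas also in the README):

* marker map: ``chrom  pos_cm  n_alleles`` — one row per marker, positions
  in cM within chromosome; the chromosome length is taken to be the last
  marker's position unless a ``# length <chrom> <cM>`` header comment says
  otherwise.
* pedigree + genotypes: ``family  id  sire  dam  role  m1_a1  m1_a2 ...`` —
  role is ``sire``/``dam``/``offspring``; parents have ``0`` for their own
  sire/dam; one column pair of (unphased) allele codes per marker, in map
  order.
* phenotypes: ``id  y`` plus optional covariate columns — only offspring
  carry phenotypes.

Mendelian consistency is verified on load.  Sampler output is a TSV with one
row per saved state, plus a small acceptance-rate report.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .genome import GenomeMap
from .ibd import attribute_alleles
from .model import ModelSpec
from .sampler import McmcConfig, SampleStore
from .simdata import Family, FamilyDataset, Qtl, TrueQtlConfig

__all__ = [
    "write_dataset", "read_dataset", "write_truth", "read_truth",
    "write_samples", "read_samples", "spec_from_dict", "mcmc_from_dict",
    "load_config",
]


# ----------------------------------------------------------------------
# dataset
# ----------------------------------------------------------------------
def write_dataset(dataset: FamilyDataset, map_path, geno_path, pheno_path):
    genome = dataset.genome
    with open(map_path, "w") as fh:
        for c in range(genome.n_chromosomes):
            fh.write(f"# length {c} {genome.lengths[c]:g}\n")
        fh.write("chrom\tpos_cm\tn_alleles\n")
        for c in range(genome.n_chromosomes):
            for p, na in zip(genome.marker_pos[c], genome.n_alleles[c]):
                fh.write(f"{c}\t{p:g}\t{na}\n")

    M = genome.n_markers
    cols = "\t".join(f"m{m + 1}_a1\tm{m + 1}_a2" for m in range(M))
    with open(geno_path, "w") as fh:
        fh.write(f"family\tid\tsire\tdam\trole\t{cols}\n")
        for f, fam in enumerate(dataset.families):
            sid, did = f"f{f}_s", f"f{f}_d"
            for label, pid, gt in ((f"{sid}", "0", fam.sire),
                                   (f"{did}", "0", fam.dam)):
                role = "sire" if label == sid else "dam"
                g = "\t".join(f"{a}\t{b}" for a, b in gt)
                fh.write(f"{f}\t{label}\t0\t0\t{role}\t{g}\n")
            for o in range(fam.n_offspring):
                g = "\t".join(f"{a}\t{b}" for a, b in fam.offspring[o])
                fh.write(f"{f}\tf{f}_o{o}\t{sid}\t{did}\toffspring\t{g}\n")

    with open(pheno_path, "w") as fh:
        k = dataset.X.shape[1]
        extra = "".join(f"\tx{c}" for c in range(1, k))
        fh.write(f"id\ty{extra}\n")
        row = 0
        for f, fam in enumerate(dataset.families):
            for o in range(fam.n_offspring):
                xs = "".join(f"\t{dataset.X[row, c]:.10g}"
                             for c in range(1, k))
                fh.write(f"f{f}_o{o}\t{fam.phenotypes[o]:.10g}{xs}\n")
                row += 1


def read_dataset(map_path, geno_path, pheno_path):
    """Load and validate a dataset; returns (FamilyDataset, GenomeMap)."""
    lengths_hint = {}
    with open(map_path) as fh:
        for line in fh:
            if line.startswith("# length"):
                _, _, c, L = line.split()
                lengths_hint[int(c)] = float(L)
            elif not line.startswith("#"):
                break
    mp = pd.read_csv(map_path, sep="\t", comment="#")
    for col in ("chrom", "pos_cm", "n_alleles"):
        if col not in mp.columns:
            raise ValueError(f"marker map is missing column {col!r}")
    chroms = sorted(mp.chrom.unique())
    marker_pos, n_alleles, lengths = [], [], []
    for c in chroms:
        sub = mp[mp.chrom == c]
        marker_pos.append(sub.pos_cm.to_numpy(dtype=float))
        n_alleles.append(sub.n_alleles.to_numpy(dtype=int))
        lengths.append(lengths_hint.get(c, float(sub.pos_cm.max())))
    genome = GenomeMap(lengths=lengths, marker_pos=marker_pos,
                       n_alleles=n_alleles)
    M = genome.n_markers

    gt = pd.read_csv(geno_path, sep="\t")
    need = ["family", "id", "sire", "dam", "role"]
    for col in need:
        if col not in gt.columns:
            raise ValueError(f"genotype table is missing column {col!r}")
    acols = [c for c in gt.columns if c not in need]
    if len(acols) != 2 * M:
        raise ValueError(f"genotype table has {len(acols)} allele columns, "
                         f"expected {2 * M} for {M} markers")
    ph = pd.read_csv(pheno_path, sep="\t").set_index("id")

    families = []
    X_rows = []
    covar_cols = [c for c in ph.columns if c != "y"]
    for famid, sub in gt.groupby("family", sort=True):
        roles = sub.set_index("role", drop=False)
        for r in ("sire", "dam"):
            if (sub.role == r).sum() != 1:
                raise ValueError(f"family {famid}: expected exactly one {r}")
        sire = sub[sub.role == "sire"][acols].to_numpy(int).reshape(M, 2)
        dam = sub[sub.role == "dam"][acols].to_numpy(int).reshape(M, 2)
        offs = sub[sub.role == "offspring"]
        if len(offs) == 0:
            raise ValueError(f"family {famid} has no offspring")
        off = offs[acols].to_numpy(int).reshape(len(offs), M, 2)
        missing = [i for i in offs.id if i not in ph.index]
        if missing:
            raise ValueError(f"unknown individual(s) in phenotype table: "
                             f"{missing}")
        yvals = ph.loc[offs.id, "y"].to_numpy(dtype=float)
        attribute_alleles(sire, dam, off, family_label=famid)
        families.append(Family(sire=sire, dam=dam, offspring=off,
                               phenotypes=yvals))
        for i in offs.id:
            X_rows.append([1.0] + [float(ph.loc[i, c]) for c in covar_cols])
    ds = FamilyDataset(families=families, genome=genome,
                       X=np.asarray(X_rows))
    return ds, genome


# ----------------------------------------------------------------------
# simulation truth sidecar
# ----------------------------------------------------------------------
def write_truth(truth: TrueQtlConfig, path):
    with open(path, "w") as fh:
        json.dump({
            "qtl": [{"chrom": q.chrom, "pos_cm": q.pos_cm,
                     "variance": q.variance} for q in truth.qtl],
            "sigma2_A": truth.sigma2_A, "sigma2_e": truth.sigma2_e,
            "mu": truth.mu,
        }, fh, indent=1)


def read_truth(path) -> TrueQtlConfig:
    with open(path) as fh:
        d = json.load(fh)
    return TrueQtlConfig(qtl=[Qtl(**q) for q in d["qtl"]],
                         sigma2_A=d["sigma2_A"], sigma2_e=d["sigma2_e"],
                         mu=d["mu"])


# ----------------------------------------------------------------------
# samples
# ----------------------------------------------------------------------
def write_samples(store: SampleStore, path, report_path=None):
    """One row per saved state; optional per-component acceptance report."""
    if store.n_samples == 0:
        raise ValueError("empty sample store")
    q = store.q
    k = store.beta.shape[1]
    cols = {}
    for c in range(k):
        cols["mu" if c == 0 else f"beta_{c}"] = store.beta[:, c]
    for j in range(q):
        cols[f"sigma2_q{j + 1}"] = store.sigma2[:, j]
    for j in range(q):
        cols[f"pos_q{j + 1}_cm"] = store.pos[:, j]
    cols["sigma2_A"] = store.sigma2_A
    cols["sigma2_e"] = store.sigma2_e
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False,
                              float_format="%.10g")
    if report_path is not None:
        with open(report_path, "w") as fh:
            fh.write("component\taccepted\tproposed\trate\n")
            for name, v in store.accept.items():
                v = np.atleast_2d(v)
                for j, (a, p) in enumerate(v):
                    rate = a / p if p else float("nan")
                    label = name if v.shape[0] == 1 else f"{name}_{j + 1}"
                    fh.write(f"{label}\t{a}\t{p}\t{rate:.4f}\n")


def read_samples(path, genome: GenomeMap = None) -> SampleStore:
    df = pd.read_csv(path, sep="\t")
    qcols = [c for c in df.columns if c.startswith("sigma2_q")]
    pcols = [c for c in df.columns if c.startswith("pos_q")]
    bcols = [c for c in df.columns
             if c == "mu" or c.startswith("beta_")]
    return SampleStore(
        beta=df[bcols].to_numpy(), sigma2=df[qcols].to_numpy(),
        pos=df[pcols].to_numpy(), sigma2_A=df["sigma2_A"].to_numpy(),
        sigma2_e=df["sigma2_e"].to_numpy(), accept={}, genome=genome)


# ----------------------------------------------------------------------
# configuration
# ----------------------------------------------------------------------
def spec_from_dict(d: dict) -> ModelSpec:
    known = {k: d[k] for k in ("q", "include_polygenic", "omega_A", "s2_A",
                               "omega_e", "s2_e", "delta") if k in d}
    return ModelSpec(**known)


def mcmc_from_dict(d: dict) -> McmcConfig:
    known = {k: d[k] for k in ("n_iter", "burnin", "thin", "nu", "nu_A",
                               "nu_e", "k_cm", "seed", "variance_floor")
             if k in d}
    return McmcConfig(**known)


def load_config(path):
    """YAML run configuration with optional ``model:`` and ``mcmc:``
    sections."""
    import yaml
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    return (spec_from_dict(d.get("model", {})),
            mcmc_from_dict(d.get("mcmc", {})), d)
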