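"""CSV readers/writers, precomputed-IBD import, and the run pipeline.

File contracts (all plain CSV with headers, positions in cM with up to 6
decimals, genotype ids opaque strings, "" and "-" both read as missing):

* map:        marker,chromosome,position
* cross:      family,parent1,parent2,type,genotype  (one row per offspring)
* genotypes:  genotype,<marker...> with "a/b" allele pairs, founders
              homozygous "a/a"; founder rows first, matching the cross
              table's parents
* phenotypes: genotype,<trait...>
* IBD long:   genotype,chromosome,position,parent,prob — the import
              contract for externally computed IBD probabilities (for
              complex pedigrees reconstructed by dedicated ancestry
              software; convert to this layout externally)
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import (
    MISSING,
    EvalGrid,
    Family,
    GeneticMap,
    InputError,
    MarkerData,
    MppDesign,
    PopType,
)
from .ibd import PLOIDY, IbdResult, calc_ibd_mpp
from .scan import (
    DEFAULT_MAX_QTL,
    DEFAULT_THRESHOLD,
    DEFAULT_WINDOW_CM,
    QtlModel,
    multi_round_scan,
)

log = logging.getLogger("mppqtl")

_MISSING_TOKENS = {"", "-", "na", "nan"}


def _read_csv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    except pd.errors.ParserError as e:
        raise InputError(f"{path}: {e}") from e
    return df


def read_genetic_map(path) -> GeneticMap:
    df = _read_csv(path)
    for col in ("marker", "chromosome", "position"):
        if col not in df.columns:
            raise InputError(f"{path}: missing column {col!r}")
    try:
        pos = df["position"].astype(float)
    except ValueError as e:
        raise InputError(f"{path}: non-numeric position: {e}") from e
    return GeneticMap(
        tuple(df["marker"]), tuple(df["chromosome"]), tuple(pos)
    )


def write_genetic_map(gmap: GeneticMap, path) -> None:
    gmap.to_frame().to_csv(path, index=False, float_format="%.6f")


def read_cross_table(path) -> MppDesign:
    df = _read_csv(path)
    for col in ("family", "parent1", "parent2", "type", "genotype"):
        if col not in df.columns:
            raise InputError(f"{path}: missing column {col!r}")
    founders: dict[str, None] = {}
    fams = []
    for fid, sub in df.groupby("family", sort=False):
        p1 = sub["parent1"].unique()
        p2 = sub["parent2"].unique()
        pt = sub["type"].unique()
        if len(p1) != 1 or len(p2) != 1 or len(pt) != 1:
            raise InputError(f"{path}: family {fid!r} has inconsistent parents/type")
        founders.setdefault(str(p1[0]))
        founders.setdefault(str(p2[0]))
        fams.append(
            Family(str(fid), str(p1[0]), str(p2[0]), PopType.parse(str(pt[0])),
                   tuple(sub["genotype"]))
        )
    return MppDesign(tuple(founders), tuple(fams))


def write_cross_table(design: MppDesign, path) -> None:
    rows = [
        (f.family_id, f.parent1, f.parent2, str(f.pop_type), g)
        for f in design.families
        for g in f.genotypes
    ]
    pd.DataFrame(
        rows, columns=["family", "parent1", "parent2", "type", "genotype"]
    ).to_csv(path, index=False)


def _parse_call(token: str, line_no: int, path) -> tuple[int, int]:
    t = token.strip()
    if t.lower() in _MISSING_TOKENS:
        return (MISSING, MISSING)
    parts = t.split("/")
    if len(parts) != 2:
        raise InputError(f"{path}: line {line_no}: bad genotype call {token!r}")
    out = []
    for p in parts:
        p = p.strip()
        if p.lower() in _MISSING_TOKENS:
            out.append(MISSING)
        else:
            try:
                out.append(int(p))
            except ValueError as e:
                raise InputError(
                    f"{path}: line {line_no}: non-integer allele {p!r}"
                ) from e
    return (out[0], out[1])


def read_genotypes(path, gmap: GeneticMap, design: MppDesign) -> MarkerData:
    """Genotype matrix: rows founders then offspring, columns = markers in
    map order.  Founders must be homozygous."""
    df = _read_csv(path)
    if "genotype" not in df.columns:
        raise InputError(f"{path}: missing 'genotype' id column")
    cols = [c for c in df.columns if c != "genotype"]
    if list(cols) != list(gmap.markers):
        raise InputError(f"{path}: marker columns do not match the map order")
    df = df.set_index("genotype")
    for f in design.founders:
        if f not in df.index:
            raise InputError(f"{path}: founder {f!r} missing")
    n_markers = gmap.n_markers
    founder_alleles = np.full((design.n_founders, n_markers), MISSING, dtype=np.int64)
    for i, f in enumerate(design.founders):
        line_no = int(np.flatnonzero(df.index == f)[0]) + 2
        for m, marker in enumerate(gmap.markers):
            a, b = _parse_call(str(df.loc[f, marker]), line_no, path)
            if a != b:
                raise InputError(
                    f"{path}: line {line_no}: founder {f!r} heterozygous at "
                    f"{marker!r} ({a}/{b}); founders must be homozygous"
                )
            founder_alleles[i, m] = a
    offspring = design.genotype_ids
    obs = np.full((len(offspring), n_markers, 2), MISSING, dtype=np.int64)
    for i, g in enumerate(offspring):
        if g not in df.index:
            raise InputError(f"{path}: genotype {g!r} missing")
        line_no = int(np.flatnonzero(df.index == g)[0]) + 2
        for m, marker in enumerate(gmap.markers):
            obs[i, m] = _parse_call(str(df.loc[g, marker]), line_no, path)
    return MarkerData(design.founders, founder_alleles, offspring, obs)


def write_genotypes(markers: MarkerData, gmap: GeneticMap, path) -> None:
    def fmt(a: int, b: int) -> str:
        if a == MISSING and b == MISSING:
            return "-"
        fa = "-" if a == MISSING else str(a)
        fb = "-" if b == MISSING else str(b)
        return f"{fa}/{fb}"

    rows = []
    for i, f in enumerate(markers.founder_ids):
        alleles = markers.founder_alleles[i]
        rows.append([f] + [fmt(a, a) for a in alleles])
    for i, g in enumerate(markers.offspring_ids):
        calls = markers.offspring_alleles[i]
        rows.append([g] + [fmt(a, b) for a, b in calls])
    pd.DataFrame(rows, columns=["genotype"] + list(gmap.markers)).to_csv(
        path, index=False
    )


def read_phenotypes(path, trait: str | None = None) -> pd.Series:
    df = _read_csv(path)
    if "genotype" not in df.columns:
        raise InputError(f"{path}: missing 'genotype' id column")
    traits = [c for c in df.columns if c != "genotype"]
    if not traits:
        raise InputError(f"{path}: no trait columns")
    if trait is None:
        trait = traits[0]
    if trait not in traits:
        raise InputError(f"{path}: trait {trait!r} not found (have {traits})")
    vals = df[trait].map(
        lambda t: np.nan if str(t).strip().lower() in _MISSING_TOKENS else float(t)
    )
    return pd.Series(vals.to_numpy(dtype=float), index=pd.Index(df["genotype"]), name=trait)


def write_phenotypes(y: pd.Series, path) -> None:
    pd.DataFrame({"genotype": y.index, y.name or "trait": y.to_numpy()}).to_csv(
        path, index=False, float_format="%.6f"
    )


# ---------------------------------------------------------------------------
# Long-format IBD import/export
# ---------------------------------------------------------------------------

_SUM_TOL = 1e-4


def write_ibd_long(ibd: IbdResult, path) -> None:
    ibd.to_long_frame().to_csv(path, index=False, float_format="%.12g")


def read_ibd_long(path) -> IbdResult:
    """Import precomputed IBD probabilities from the long CSV format.

    Columns: genotype,chromosome,position,parent,prob.  Probabilities are
    converted to expected allele counts (x ploidy); per (genotype,
    position) the parent probabilities must sum to 1 within 1e-4 and are
    renormalised to sum exactly.
    """
    df = _read_csv(path)
    for col in ("genotype", "chromosome", "position", "parent", "prob"):
        if col not in df.columns:
            raise InputError(f"{path}: missing column {col!r}")
    df = df.assign(
        position=df["position"].astype(float), prob=df["prob"].astype(float)
    )
    dup = df.duplicated(["genotype", "chromosome", "position", "parent"])
    if dup.any():
        bad = df[dup].head(5)
        raise InputError(
            f"{path}: duplicate (genotype, position, parent) rows, e.g.\n{bad}"
        )
    genotypes = tuple(dict.fromkeys(df["genotype"]))
    parents = tuple(sorted(df["parent"].unique()))
    pos_df = (
        df[["chromosome", "position"]]
        .drop_duplicates()
        .sort_values(["chromosome", "position"], kind="stable")
    )
    # keep chromosome first-appearance order from the file
    chrom_order = list(dict.fromkeys(df["chromosome"]))
    pos_df["__c"] = pos_df["chromosome"].map(chrom_order.index)
    pos_df = pos_df.sort_values(["__c", "position"], kind="stable")
    grid = EvalGrid(
        tuple(pos_df["chromosome"]),
        tuple(pos_df["position"]),
        tuple(False for _ in range(len(pos_df))),
    )
    g_code = {g: i for i, g in enumerate(genotypes)}
    p_code = {p: i for i, p in enumerate(parents)}
    l_code = {
        (c, p): i
        for i, (c, p) in enumerate(zip(pos_df["chromosome"], pos_df["position"]))
    }
    counts = np.zeros((len(genotypes), len(l_code), len(parents)))
    gi = df["genotype"].map(g_code).to_numpy()
    li = [l_code[(c, p)] for c, p in zip(df["chromosome"], df["position"])]
    pi = df["parent"].map(p_code).to_numpy()
    counts[gi, li, pi] = df["prob"].to_numpy() * PLOIDY
    sums = counts.sum(axis=2) / PLOIDY
    bad = np.abs(sums - 1.0) > _SUM_TOL
    if bad.any():
        g_bad, l_bad = np.nonzero(bad)
        msgs = [
            f"  genotype {genotypes[g]!r} at {grid.chromosomes[l]}:{grid.positions[l]} "
            f"sums to {sums[g, l]:.6f}"
            for g, l in list(zip(g_bad, l_bad))[:5]
        ]
        raise InputError(
            f"{path}: parent probabilities do not sum to 1:\n" + "\n".join(msgs)
        )
    counts /= sums[:, :, None]  # renormalise residual rounding
    return IbdResult(genotypes, grid, parents, counts)


def write_profile(profile_frame: pd.DataFrame, path) -> None:
    profile_frame.to_csv(path, index=False, float_format="%.10g")


def read_profile(path) -> pd.DataFrame:
    df = _read_csv(path)
    for col in ("chromosome", "position", "lrt", "p", "minus_log10_p"):
        if col not in df.columns:
            raise InputError(f"{path}: missing column {col!r}")
    return df.astype(
        {"position": float, "lrt": float, "p": float, "minus_log10_p": float}
    )


def write_qtl_tables(model: QtlModel, qtl_path, effects_path) -> None:
    model.qtl_frame().to_csv(qtl_path, index=False, float_format="%.10g")
    model.effects.to_csv(effects_path, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Run configuration and pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration of a full mapping run.

    Exactly one of (``genotypes``) or (``ibd_import``) must be supplied:
    either IBD probabilities are computed from marker genotypes, or a
    precomputed long-format IBD table is imported.
    """

    map_path: str | None = None
    genotypes: str | None = None
    cross_table: str | None = None
    phenotypes: str | None = None
    ibd_import: str | None = None
    trait: str | None = None
    step_cM: float = 5.0
    error_rate: float = 0.01
    threshold: float = DEFAULT_THRESHOLD
    window_cM: float = DEFAULT_WINDOW_CM
    max_qtl: int = DEFAULT_MAX_QTL
    use_kinship: bool = False
    seed: int = 1
    output_dir: str = "mppqtl_out"

    def __post_init__(self) -> None:
        if (self.genotypes is None) == (self.ibd_import is None):
            raise InputError(
                "exactly one of genotype inputs or an IBD import must be supplied"
            )
        if self.genotypes is not None and self.map_path is None:
            raise InputError("a genetic map is required with genotype inputs")
        if self.cross_table is None or self.phenotypes is None:
            raise InputError("cross table and phenotypes are required")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise InputError(f"{path}: config must be a flat key-value mapping")
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise InputError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)


def run_pipeline(config: RunConfig) -> QtlModel:
    """Full run: IBD calculation (or import) -> multi-round scan -> CSVs.

    Writes profile.csv, qtl.csv, effects.csv and run.log into the output
    directory and returns the fitted QTL model.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info("mppqtl %s", __version__)
        log.info("numpy %s, pandas %s", np.__version__, pd.__version__)
        for key, val in vars(config).items():
            log.info("config %s = %r", key, val)
        stage = "read inputs"
        try:
            design = read_cross_table(config.cross_table)
            y = read_phenotypes(config.phenotypes, config.trait)
            if config.ibd_import is not None:
                stage = "IBD import"
                ibd = read_ibd_long(config.ibd_import)
            else:
                stage = "IBD calculation"
                gmap = read_genetic_map(config.map_path)
                markers = read_genotypes(config.genotypes, gmap, design)
                ibd = calc_ibd_mpp(
                    gmap, markers, design, config.step_cM, config.error_rate
                )
            stage = "QTL scan"
            model = multi_round_scan(
                ibd,
                y,
                design,
                threshold=config.threshold,
                window_cM=config.window_cM,
                max_qtl=config.max_qtl,
                use_kinship=config.use_kinship,
            )
            stage = "write outputs"
            write_profile(model.final_profile.frame, out / "profile.csv")
            write_qtl_tables(model, out / "qtl.csv", out / "effects.csv")
            log.info(
                "finished: %d QTL in %d round(s)", len(model.qtls), model.n_rounds
            )
            return model
        except Exception as e:
            log.error("stage %r failed: %s", stage, e)
            raise
    finally:
        log.removeHandler(handler)
        handler.close()


def write_simulation(
    outdir,
    design: MppDesign,
    gmap: GeneticMap,
    markers: MarkerData,
    truth,
    y: pd.Series,
) -> None:
    """Write the standard input CSVs plus a JSON truth sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_genetic_map(gmap, outdir / "map.csv")
    write_cross_table(design, outdir / "cross.csv")
    write_genotypes(markers, gmap, outdir / "genotypes.csv")
    write_phenotypes(y, outdir / "phenotypes.csv")
    sidecar = {
        "seed": truth.seed,
        "founders": list(truth.founders),
        "beta": truth.beta,
        "sigma_eps": truth.sigma_eps,
        "qtls": [
            {
                "chromosome": q.chromosome,
                "position_cM": q.position_cM,
                "effects": eff,
            }
            for q, eff in zip(truth.qtls, truth.qtl_effects)
        ],
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)
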