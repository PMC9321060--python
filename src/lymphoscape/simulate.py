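"""Synthetic lymphoma cohort generator with planted co-expression modules.

The generator emulates the structure of a large germinal-center lymphoma
cohort profiled on expression microarrays: ten-plus subtype strata in the
published proportions, ten planted co-expression modules (the counterparts of
the over-expression spots A..K of the SOM landscape), a subtype-by-module
activation matrix encoding which modules are up or down in which subtype, a
continuum between subtypes realized as per-sample jitter of the activation
vector, and additive Gaussian measurement noise, all on log2 scale:

    x[g, s] = mu_g + a~[s, m(g)] * e_m(g) + eps[g, s]

with gene baseline mu_g ~ N(8, 1), realized activation a~[s, .] =
a[subtype(s), .] + N(0, sigma_act^2), module effect e_m in log2 units, and
eps ~ N(0, sigma_eps^2). Background genes carry no module term. All
randomness derives from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, Signature

__all__ = [
    "ModuleDef",
    "CohortSpec",
    "CohortTruth",
    "MMML_STRATA",
    "DEFAULT_MODULE_SIZES",
    "DEFAULT_ACTIVATION",
    "LITERATURE_SIGNATURES",
    "default_mmml_spec",
    "generate_cohort",
    "make_reference_signatures",
]

#: Published per-stratum case counts of the reference cohort (ten major
#: strata, with DLBCL further split into COO groups and double-hit cases).
MMML_STRATA: dict[str, int] = {
    "BL": 74,
    "DLBCL-GCB": 142,
    "DLBCL-ABC": 133,
    "DLBCL-unclassified": 97,
    "DHL": 58,
    "FL": 145,
    "intermediate": 81,
    "FL/DLBCL": 48,
    "PMBL": 23,
    "MM": 20,
    "IRF4-LCL": 10,
    "mnBLL-11q": 6,
    "MCL": 4,
}

#: Strata constituting classical (non-double-hit) DLBCL in two-group contrasts.
DLBCL_LIKE = ("DLBCL-GCB", "DLBCL-ABC", "DLBCL-unclassified")

#: Planted module sizes. D and E carry the printed extremes of the spot-module
#: size range (1154 and 129 genes); the others span the range in between.
DEFAULT_MODULE_SIZES: dict[str, int] = {
    "A": 600, "B": 400, "C": 200, "D": 1154, "E": 129,
    "F": 700, "G": 350, "H": 300, "I": 450, "K": 250,
}

# Subtype x module activation (sign = direction, magnitude = strength).
# Signs follow the spot-expression heatmap logic of the landscape: BL up in
# A/B/D (and the BL-resembling C), down in the inflammation module F; DLBCL up
# in F/G, with G the stroma/microenvironment module shared with FL; ABC
# additionally in the plasma-cell module H; GCB moderately in A and the
# B-cell module K; DHL with a marked singular over-expression of A (stronger
# than GCB/FL, which carry it "to a lesser degree"), moderate proliferation D
# and down F; FL up in the stromal modules I/G plus A/K; "intermediate" is
# the 50/50 mixture of the BL and generic-DLBCL rows; mnBLL-11q is
# BL-resembling (D, C) with elevated E/K; IRF4-LCL carries E (PIM1) with
# proliferative and plasma-cell traits; MM is plasma-cell only.
DEFAULT_ACTIVATION: dict[str, dict[str, float]] = {
    "BL":                 {"A": 1.0, "B": 1.0, "C": 0.75, "D": 1.0, "F": -1.0},
    "DLBCL-GCB":          {"A": 0.5, "F": 1.0, "G": 1.0, "K": 0.5},
    "DLBCL-ABC":          {"F": 1.0, "G": 0.5, "H": 1.0},
    "DLBCL-unclassified": {"A": 0.25, "F": 1.0, "G": 1.0, "H": 0.5},
    "DHL":                {"A": 1.0, "D": 0.5, "F": -1.0},
    "FL":                 {"A": 0.5, "G": 0.75, "I": 1.0, "K": 0.5},
    "intermediate":       {"A": 0.5, "B": 0.5, "C": 0.375, "D": 0.5, "G": 0.5},
    "FL/DLBCL":           {"A": 0.25, "F": 0.5, "G": 0.5, "I": 0.5, "K": 0.25},
    "PMBL":               {"F": 1.0, "G": 0.25},
    "MM":                 {"H": 1.0},
    "IRF4-LCL":           {"D": 0.5, "E": 1.0, "G": 0.5, "H": 0.5},
    "mnBLL-11q":          {"A": 0.5, "B": 0.25, "C": 1.0, "D": 1.0, "E": 0.5, "K": 0.5},
    "MCL":                {"C": 0.5},
}

#: Emulated literature classifier sets: name -> (source module letter, size).
#: Sizes follow the printed classifier-set cardinalities; sources follow the
#: spot each literature set accumulates in (BL_up -> B, DLBCL_up -> F,
#: ABC_up -> H, GCB_up/DHL_up -> A).
LITERATURE_SIGNATURES: dict[str, tuple[str, int]] = {
    "hummel_BL_up": ("B", 47),
    "hummel_DLBCL_up": ("F", 18),
    "sha_BL_up": ("B", 16),
    "sha_DLBCL_up": ("F", 11),
    "masque_BL_up": ("B", 6),
    "masque_DLBCL_up": ("F", 4),
    "masque_ABC_up": ("H", 9),
    "masque_GCB_up": ("A", 11),
    "scott_ABC_up": ("H", 7),
    "scott_GCB_up": ("A", 6),
    "wright_ABC_up": ("H", 13),
    "wright_GCB_up": ("A", 7),
    "ennishi_DHL_up": ("A", 31),
    "ennishi_nonDHL_up": ("F", 47),
}


@dataclass(frozen=True)
class ModuleDef:
    """A planted co-expression module (counterpart of a landscape spot)."""

    letter: str
    gene_count: int
    effect: float = 1.0  # log2 units

    def __post_init__(self) -> None:
        if self.gene_count < 10:
            raise ValueError(f"module {self.letter}: gene_count must be >= 10")


@dataclass
class CohortSpec:
    """Everything needed to draw one synthetic cohort."""

    strata: dict[str, int]
    modules: list[ModuleDef]
    activation: pd.DataFrame  # strata x module letters, values in [-1, 1]
    sigma_act: float = 0.15   # per-sample activation jitter (the continuum)
    sigma_noise: float = 0.5  # per-entry Gaussian noise, log2 units
    background_genes: int = 15467
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.strata.values()):
            raise ValueError("all stratum sample counts must be positive")
        letters = [m.letter for m in self.modules]
        if len(set(letters)) != len(letters):
            raise ValueError("module letters must be unique")
        if self.sigma_act < 0 or self.sigma_noise < 0:
            raise ValueError("sigma_act and sigma_noise must be >= 0")
        if self.background_genes < 0:
            raise ValueError("background_genes must be >= 0")
        missing = set(self.strata) - set(self.activation.index)
        if missing:
            raise ValueError(f"activation matrix misses strata: {sorted(missing)}")
        missing_mod = set(letters) - set(self.activation.columns)
        if missing_mod:
            raise ValueError(f"activation matrix misses modules: {sorted(missing_mod)}")
        a = self.activation.to_numpy(dtype=float)
        if np.abs(a).max() > 1.0 + 1e-12:
            raise ValueError("activation values must lie in [-1, 1]")

    @property
    def n_samples(self) -> int:
        return sum(self.strata.values())

    @property
    def n_genes(self) -> int:
        return sum(m.gene_count for m in self.modules) + self.background_genes


@dataclass
class CohortTruth:
    """Ground truth of a generated cohort, for recovery tests."""

    module_of_gene: dict[str, str]  # gene -> module letter or "background"
    module_genes: dict[str, list[str]]
    background_gene_ids: list[str]
    realized_activation: pd.DataFrame  # samples x module letters
    labels: dict[str, str]  # sample -> stratum

    def genes_of(self, letter: str) -> set[str]:
        return set(self.module_genes[letter])


def _largest_remainder(counts: dict[str, int], total: int) -> dict[str, int]:
    """Scale integer counts to a new total, preserving proportions.

    Largest-remainder rounding; ties broken by dict order for determinism.
    """
    base = sum(counts.values())
    raw = {k: v * total / base for k, v in counts.items()}
    out = {k: int(np.floor(r)) for k, r in raw.items()}
    short = total - sum(out.values())
    order = sorted(counts, key=lambda k: (-(raw[k] - out[k]), list(counts).index(k)))
    for k in order[:short]:
        out[k] += 1
    # keep every stratum represented at small totals
    for k in out:
        while out[k] == 0:
            donor = max(out, key=lambda j: out[j])
            out[donor] -= 1
            out[k] += 1
    return out


def default_mmml_spec(total: int = 300, seed: int = 0, *,
                      sigma_act: float = 0.15, sigma_noise: float = 0.5,
                      background_genes: int = 15467) -> CohortSpec:
    """The default study cohort: published strata proportions scaled to
    ``total`` samples, ten planted modules A..K, and the default activation
    matrix. At ``total == sum(MMML_STRATA.values())`` (841) the printed
    per-stratum counts are reproduced exactly."""
    strata = _largest_remainder(MMML_STRATA, total)
    modules = [ModuleDef(letter, n) for letter, n in DEFAULT_MODULE_SIZES.items()]
    letters = [m.letter for m in modules]
    act = pd.DataFrame(0.0, index=list(MMML_STRATA), columns=letters)
    for stratum, row in DEFAULT_ACTIVATION.items():
        for letter, a in row.items():
            act.loc[stratum, letter] = a
    return CohortSpec(strata=strata, modules=modules, activation=act,
                      sigma_act=sigma_act, sigma_noise=sigma_noise,
                      background_genes=background_genes, seed=seed)


def generate_cohort(spec: CohortSpec) -> tuple[ExpressionMatrix, CohortTruth]:
    """Draw an expression matrix and its ground truth from a cohort spec."""
    rng = np.random.default_rng(spec.seed)
    letters = [m.letter for m in spec.modules]
    effects = np.array([m.effect for m in spec.modules])

    gene_ids: list[str] = []
    module_of_gene: dict[str, str] = {}
    module_genes: dict[str, list[str]] = {}
    module_index = np.empty(spec.n_genes, dtype=int)  # -1 = background
    pos = 0
    for mi, mod in enumerate(spec.modules):
        ids = [f"g{pos + j:05d}" for j in range(mod.gene_count)]
        module_genes[mod.letter] = ids
        for g in ids:
            module_of_gene[g] = mod.letter
        module_index[pos:pos + mod.gene_count] = mi
        gene_ids.extend(ids)
        pos += mod.gene_count
    background_ids = [f"g{pos + j:05d}" for j in range(spec.background_genes)]
    for g in background_ids:
        module_of_gene[g] = "background"
    module_index[pos:] = -1
    gene_ids.extend(background_ids)

    sample_ids: list[str] = []
    labels: dict[str, str] = {}
    for stratum, n in spec.strata.items():
        for _ in range(n):
            sid = f"s{len(sample_ids):04d}"
            sample_ids.append(sid)
            labels[sid] = stratum

    a_rows = spec.activation.loc[[labels[s] for s in sample_ids], letters].to_numpy(dtype=float)
    realized = a_rows + rng.normal(0.0, spec.sigma_act, size=a_rows.shape)

    mu = rng.normal(spec.baseline_mean, spec.baseline_sd, size=spec.n_genes)
    x = np.tile(mu[:, None], (1, len(sample_ids)))
    in_module = module_index >= 0
    # module term: realized activation of the gene's module, scaled by e_m
    x[in_module, :] += (realized[:, module_index[in_module]].T
                        * effects[module_index[in_module]][:, None])
    x += rng.normal(0.0, spec.sigma_noise, size=x.shape)

    em = ExpressionMatrix(gene_ids, sample_ids, x, sample_labels=labels)
    truth = CohortTruth(
        module_of_gene=module_of_gene,
        module_genes=module_genes,
        background_gene_ids=background_ids,
        realized_activation=pd.DataFrame(realized, index=sample_ids, columns=letters),
        labels=labels,
    )
    return em, truth


def make_reference_signatures(truth: CohortTruth,
                              sizes: dict[str, int] | None = None,
                              decoy_fraction: float = 0.1,
                              seed: int = 0,
                              sources: dict[str, str] | None = None,
                              ) -> list[Signature]:
    """Emulate literature classifier sets as seeded samples of planted
    module genes plus background decoys.

    Each emitted signature draws ``round((1 - decoy_fraction) * size)`` genes
    from its source module and the remainder from background genes, without
    replacement. Defaults emulate the published classifier catalogue
    (``LITERATURE_SIGNATURES``) with its printed set sizes.
    """
    if not 0.0 <= decoy_fraction < 0.5:
        raise ValueError("decoy_fraction must lie in [0, 0.5)")
    if sizes is None:
        catalog = dict(LITERATURE_SIGNATURES)
    else:
        src = sources or {}
        catalog = {}
        for name, size in sizes.items():
            if name in src:
                catalog[name] = (src[name], size)
            elif name in LITERATURE_SIGNATURES:
                catalog[name] = (LITERATURE_SIGNATURES[name][0], size)
            else:
                raise ValueError(f"no source module known for signature {name!r}")
    rng = np.random.default_rng(seed)
    out: list[Signature] = []
    for name, (letter, size) in catalog.items():
        if letter not in truth.module_genes:
            raise ValueError(f"signature {name!r}: unknown source module {letter!r}")
        pool = truth.module_genes[letter]
        n_decoy = int(round(decoy_fraction * size))
        n_core = size - n_decoy
        if n_core > len(pool):
            raise ValueError(
                f"signature {name!r}: requested {n_core} genes but module "
                f"{letter} holds only {len(pool)}"
            )
        if n_decoy > len(truth.background_gene_ids):
            raise ValueError(f"signature {name!r}: not enough background genes for decoys")
        core = rng.choice(pool, size=n_core, replace=False)
        decoys = rng.choice(truth.background_gene_ids, size=n_decoy, replace=False)
        direction = "down" if name.lower().endswith("_down") else "up"
        out.append(Signature(name, direction, frozenset(core) | frozenset(decoys),
                             provenance=f"emulated from module {letter}, decoy_fraction={decoy_fraction}"))
    return out
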