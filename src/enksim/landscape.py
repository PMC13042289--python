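"""NK submodels and E(NK) ensembles of tunably epistatic fitness landscapes.

A complex trait is modelled as the mean of ``N`` *fitness components*. Each
component is a random function of the diploid genotypes (dosages 0/1/2) at a
small set of interacting genes; its values are i.i.d. Uniform(0, 1) across
distinct genotype configurations and components. The mean interaction degree
``K`` tunes ruggedness: at ``K = 1`` every component depends on exactly one
gene and acts strictly additively (heterozygote midway between homozygotes);
at larger ``K`` component sizes are Poisson(``K``) truncated to [1, 15] and
genes act pleiotropically and epistatically.

Genotype-by-environment interaction is introduced by an ensemble of ``E = 12``
NK submodels, one per discrete environment type (ET) on an ordinal scale.
Adjacent ETs share 75% of their fitness components, so the genetic correlation
between ET-specific fitness decays roughly as ``0.75 ** lag``.

The component random functions are realized with a counter-based keyed integer
hash (splitmix64-style finalizer) of the component's 64-bit uid and the packed
member dosages, mapped to [0, 1). Evaluation is therefore stateless, O(1) per
component, bit-reproducible from the master seed, and identical whether or not
values are cached.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from enksim.exceptions import (
    ArchitectureError,
    ConfigurationError,
    InvalidGenotypeError,
)

N_LOCI_DEFAULT = 500
N_ET_DEFAULT = 12
MAX_COMPONENT_SIZE = 15
RETAIN_FRACTION_DEFAULT = 0.75

_U64 = np.uint64
_GAMMA = _U64(0x9E3779B97F4A7C15)
_M1 = _U64(0xBF58476D1CE4E5B9)
_M2 = _U64(0x94D049BB133111EB)
_POW3 = (3 ** np.arange(MAX_COMPONENT_SIZE, dtype=np.uint64)).astype(np.uint64)
_INV53 = 1.0 / (1 << 53)


def _finalize(z: np.ndarray) -> np.ndarray:
    z = (z ^ (z >> _U64(30))) * _M1
    z = (z ^ (z >> _U64(27))) * _M2
    return z ^ (z >> _U64(31))


def _hash_u01(uid, code):
    """Keyed hash of (uid, packed dosage code) to a float in [0, 1)."""
    with np.errstate(over="ignore"):  # modular uint64 arithmetic is intended
        z = np.asarray(uid, dtype=np.uint64) + np.asarray(code, dtype=np.uint64) * _GAMMA
        z = _finalize(z)
        z = _finalize(z ^ _GAMMA)
    return (z >> _U64(11)).astype(np.float64) * _INV53


_UNION_KERNEL = None
_UNION_KERNEL_TRIED = False


def _get_union_kernel():
    """Compiled batch evaluator for component values (numba; None if absent).

    The kernel computes exactly the same keyed hash as `_hash_u01`, so cached,
    compiled, and pure-numpy evaluations are bit-identical.
    """
    global _UNION_KERNEL, _UNION_KERNEL_TRIED
    if _UNION_KERNEL_TRIED:
        return _UNION_KERNEL
    _UNION_KERNEL_TRIED = True
    try:
        import numba

        @numba.njit(cache=False, fastmath=False)
        def kernel(D, members, sizes, uids, out):  # pragma: no cover - compiled
            G, U = out.shape
            gamma = np.uint64(0x9E3779B97F4A7C15)
            m1 = np.uint64(0xBF58476D1CE4E5B9)
            m2 = np.uint64(0x94D049BB133111EB)
            inv = 1.0 / 9007199254740992.0
            for g in range(G):
                for c in range(U):
                    code = np.uint64(0)
                    p = np.uint64(1)
                    for j in range(sizes[c]):
                        code += np.uint64(D[g, members[c, j]]) * p
                        p *= np.uint64(3)
                    z = uids[c] + code * gamma
                    z = (z ^ (z >> np.uint64(30))) * m1
                    z = (z ^ (z >> np.uint64(27))) * m2
                    z = z ^ (z >> np.uint64(31))
                    z = z ^ gamma
                    z = (z ^ (z >> np.uint64(30))) * m1
                    z = (z ^ (z >> np.uint64(27))) * m2
                    z = z ^ (z >> np.uint64(31))
                    out[g, c] = (z >> np.uint64(11)) * inv
        _UNION_KERNEL = kernel
    except Exception:
        _UNION_KERNEL = None
    return _UNION_KERNEL


def _pack_dosages(member_dosages: np.ndarray) -> np.uint64:
    d = np.asarray(member_dosages, dtype=np.uint64)
    return _U64((d * _POW3[: d.size]).sum())


def random_function_value(uid: int, member_dosages) -> float:
    """Uniform(0,1) value of a component random function.

    Deterministic in ``(uid, member_dosages)``; values for distinct keys are
    statistically independent. ``member_dosages`` is the genotype restricted
    to the component's member loci (1-15 entries in {0, 1, 2}).
    """
    d = np.asarray(member_dosages)
    if d.size < 1 or d.size > MAX_COMPONENT_SIZE:
        raise InvalidGenotypeError(
            f"component genotype must have 1-{MAX_COMPONENT_SIZE} entries, got {d.size}"
        )
    if not np.isin(d, (0, 1, 2)).all():
        raise InvalidGenotypeError("dosages must be in {0, 1, 2}")
    return float(_hash_u01(np.uint64(uid), _pack_dosages(d)))


@dataclass(frozen=True)
class FitnessComponent:
    """One fitness component: a random function of the genotypes at its members.

    ``uid`` is an opaque 64-bit identifier that seeds the component's random
    function; retained components keep their uid (and hence all their values)
    when carried from one ET's submodel to the next.
    """

    uid: int
    members: np.ndarray  # locus indices, shape (size,), 1 <= size <= 15

    def __post_init__(self):
        m = np.asarray(self.members, dtype=np.int64)
        if m.size < 1 or m.size > MAX_COMPONENT_SIZE:
            raise ArchitectureError(f"component size {m.size} outside [1, 15]")
        if np.unique(m).size != m.size:
            raise ArchitectureError("component member loci must be unique")
        object.__setattr__(self, "members", m)

    @property
    def size(self) -> int:
        return int(self.members.size)


class NKSubmodel:
    """One NK fitness landscape: exactly ``n_loci`` components over ``n_loci`` genes."""

    def __init__(self, components, n_loci: int, k_target: int):
        if len(components) != n_loci:
            raise ArchitectureError(
                f"expected {n_loci} components, got {len(components)}"
            )
        for c in components:
            if (c.members < 0).any() or (c.members >= n_loci).any():
                raise ArchitectureError("component member index out of range")
        self.components = list(components)
        self.n_loci = n_loci
        self.k_target = k_target
        self.additive_mode = k_target == 1
        if self.additive_mode:
            sizes = {c.size for c in self.components}
            owners = np.concatenate([c.members for c in self.components])
            if sizes != {1} or np.unique(owners).size != n_loci:
                raise ArchitectureError(
                    "K=1 submodel must assign each locus to exactly one "
                    "single-member component"
                )
        # padded member/power tables for vectorized evaluation
        self._uids = np.array([c.uid for c in self.components], dtype=np.uint64)
        self._members_pad = np.zeros((n_loci, MAX_COMPONENT_SIZE), dtype=np.int64)
        self._pow3 = np.zeros((n_loci, MAX_COMPONENT_SIZE), dtype=np.uint64)
        for i, c in enumerate(self.components):
            self._members_pad[i, : c.size] = c.members
            self._pow3[i, : c.size] = _POW3[: c.size]
        self._additive_table = (
            self._build_additive_table() if self.additive_mode else None
        )

    def _build_additive_table(self) -> np.ndarray:
        """Per-locus value table T[l, d] for the strictly additive K=1 case."""
        locus_of = np.empty(self.n_loci, dtype=np.int64)
        uid_of = np.empty(self.n_loci, dtype=np.uint64)
        for c in self.components:
            locus_of[c.members[0]] = c.members[0]
            uid_of[c.members[0]] = c.uid
        v0 = _hash_u01(uid_of, np.zeros(self.n_loci, dtype=np.uint64))
        v2 = _hash_u01(uid_of, np.full(self.n_loci, 2, dtype=np.uint64))
        return np.stack([v0, (v0 + v2) / 2.0, v2], axis=1)

    def component_values(self, dosages: np.ndarray) -> np.ndarray:
        """Values of all components for a batch of genotypes.

        Parameters
        ----------
        dosages : (G, n_loci) or (n_loci,) integer array with entries in {0,1,2}.

        Returns
        -------
        (G, n_loci) array of component values in [0, 1).
        """
        D = _check_dosages(dosages, self.n_loci)
        codes = np.zeros((D.shape[0], self.n_loci), dtype=np.uint64)
        for j in range(MAX_COMPONENT_SIZE):
            codes += D[:, self._members_pad[:, j]].astype(np.uint64) * self._pow3[:, j]
        vals = _hash_u01(self._uids[None, :], codes)
        if self.additive_mode:
            # heterozygote midway between the two homozygotes
            het = D[:, self._members_pad[:, 0]] == 1
            vals = np.where(het, self._additive_table[:, 1][self._members_pad[:, 0]], vals)
        return vals

    def fitness_batch(self, dosages: np.ndarray) -> np.ndarray:
        """Fitness (mean component value) for a batch of genotypes."""
        D = _check_dosages(dosages, self.n_loci)
        if self.additive_mode:
            T = self._additive_table
            return T[np.arange(self.n_loci)[None, :], D].mean(axis=1)
        return self.component_values(D).mean(axis=1)


def _check_dosages(dosages, n_loci: int) -> np.ndarray:
    D = np.asarray(dosages)
    if D.ndim == 1:
        D = D[None, :]
    if D.shape[1] != n_loci:
        raise InvalidGenotypeError(
            f"genotype length {D.shape[1]} != n_loci {n_loci}"
        )
    if D.min() < 0 or D.max() > 2:
        raise InvalidGenotypeError("dosages must be in {0, 1, 2}")
    return D.astype(np.int64, copy=False)


def component_value(
    submodel: NKSubmodel, component: FitnessComponent, genotype
) -> float:
    """Value of a single component for one genotype.

    Under the model-level additive mode (``K = 1``) the heterozygote value is
    the arithmetic mean of the two homozygote values; otherwise the raw random
    function value is returned (so single-member components under ``K > 1``
    carry free dominance deviations).
    """
    g = _check_dosages(genotype, submodel.n_loci)[0]
    d = g[component.members]
    if submodel.additive_mode and d[0] == 1:
        v0 = random_function_value(component.uid, [0])
        v2 = random_function_value(component.uid, [2])
        return (v0 + v2) / 2.0
    return random_function_value(component.uid, d)


def fitness(submodel: NKSubmodel, genotype) -> float:
    """Fitness of one genotype: mean of the component values, in [0, 1]."""
    return float(submodel.fitness_batch(genotype)[0])


def build_nk_submodel(
    n_loci: int, k_target: int, rng: np.random.Generator
) -> NKSubmodel:
    """Construct one NK submodel.

    At ``k_target = 1`` the gene-to-component assignment is a uniform random
    bijection. For larger ``k_target`` component sizes are Poisson(K) samples
    conditioned on [1, 15] and members are drawn uniformly without replacement.
    """
    if not 1 <= k_target <= MAX_COMPONENT_SIZE:
        raise ConfigurationError(f"k_target must be in [1, 15], got {k_target}")
    uids = rng.integers(
        0, np.iinfo(np.uint64).max, size=n_loci, dtype=np.uint64, endpoint=True
    )
    components = _sample_components(n_loci, k_target, uids, rng)
    return NKSubmodel(components, n_loci, k_target)


def _sample_components(n_loci, k_target, uids, rng) -> list:
    if k_target == 1:
        perm = rng.permutation(n_loci)
        return [
            FitnessComponent(int(uids[i]), np.array([perm[i]]))
            for i in range(n_loci)
        ]
    # members are drawn without replacement, so sizes cannot exceed n_loci
    # (only relevant for tiny toy landscapes)
    sizes = np.minimum(_truncated_poisson(k_target, n_loci, rng), n_loci)
    return [
        FitnessComponent(int(uids[i]), rng.choice(n_loci, size=sizes[i], replace=False))
        for i in range(n_loci)
    ]


def _truncated_poisson(rate, size, rng) -> np.ndarray:
    """Poisson(rate) samples conditioned on the range [1, 15]."""
    out = rng.poisson(rate, size=size)
    bad = (out < 1) | (out > MAX_COMPONENT_SIZE)
    while bad.any():
        out[bad] = rng.poisson(rate, size=int(bad.sum()))
        bad = (out < 1) | (out > MAX_COMPONENT_SIZE)
    return out


class ENKModel:
    """Ensemble of ``n_et`` NK submodels with component lineage across ETs.

    Adjacent ETs share ``round(retain_fraction * N)`` components (identical
    uids, hence identical values); the remainder are assembled anew. Fitness
    evaluation across all ETs deduplicates shared components.
    """

    def __init__(self, submodels, retain_fraction: float, master_seed: int):
        self.submodels = list(submodels)
        self.retain_fraction = retain_fraction
        self.master_seed = master_seed
        self.n_et = len(self.submodels)
        self.n_loci = self.submodels[0].n_loci
        self.k_target = self.submodels[0].k_target
        self.additive_mode = self.submodels[0].additive_mode
        self._build_union()

    def _build_union(self):
        uid_row: dict[int, int] = {}
        comps: list[FitnessComponent] = []
        self._et_rows = np.zeros((self.n_et, self.n_loci), dtype=np.int64)
        for e, sm in enumerate(self.submodels):
            for i, c in enumerate(sm.components):
                row = uid_row.get(c.uid)
                if row is None:
                    row = len(comps)
                    uid_row[c.uid] = row
                    comps.append(c)
                self._et_rows[e, i] = row
        U = len(comps)
        # order union components by size (descending) so that the packed-code
        # accumulation can stop at each component's true size
        sizes = np.array([c.size for c in comps])
        order = np.argsort(-sizes, kind="stable")
        rank_of = np.empty(U, dtype=np.int64)
        rank_of[order] = np.arange(U)
        comps = [comps[i] for i in order]
        self._et_rows = rank_of[self._et_rows]
        self._u_uids = np.array([c.uid for c in comps], dtype=np.uint64)
        self._u_members = np.zeros((U, MAX_COMPONENT_SIZE), dtype=np.int64)
        self._u_pow3 = np.zeros((U, MAX_COMPONENT_SIZE), dtype=np.uint64)
        for i, c in enumerate(comps):
            self._u_members[i, : c.size] = c.members
            self._u_pow3[i, : c.size] = _POW3[: c.size]
        sizes = sizes[order]
        self._u_sizes = sizes.astype(np.int64)
        self._n_with_size_gt = np.array(
            [(sizes > j).sum() for j in range(MAX_COMPONENT_SIZE)], dtype=np.int64
        )
        # ET incidence of each unique component, for TPE-weighted evaluation
        self._incidence = np.zeros((U, self.n_et))
        for e in range(self.n_et):
            self._incidence[self._et_rows[e], e] += 1.0
        if self.additive_mode:
            self._additive_tables = np.stack(
                [sm._additive_table for sm in self.submodels]
            )

    def _union_values(self, D: np.ndarray) -> np.ndarray:
        """Values of all unique components for a batch of genotypes (G, U)."""
        kernel = _get_union_kernel()
        if kernel is not None:
            out = np.empty((D.shape[0], self._u_uids.size))
            kernel(
                np.ascontiguousarray(D, dtype=np.uint8),
                self._u_members, self._u_sizes, self._u_uids, out,
            )
            return out
        G = D.shape[0]
        Du = D.astype(np.uint64)
        codes = np.zeros((G, self._u_uids.size), dtype=np.uint64)
        for j in range(MAX_COMPONENT_SIZE):
            nj = self._n_with_size_gt[j]
            if nj == 0:
                break
            codes[:, :nj] += Du[:, self._u_members[:nj, j]] * self._u_pow3[:nj, j]
        return _hash_u01(self._u_uids[None, :], codes)

    def fitness_all_ets(self, dosages) -> np.ndarray:
        """Fitness of a batch of genotypes in every ET.

        Returns an array of shape ``(G, n_et)``.
        """
        D = _check_dosages(dosages, self.n_loci)
        G = D.shape[0]
        if self.additive_mode:
            idx = np.arange(self.n_loci)[None, :]
            return np.stack(
                [self._additive_tables[e][idx, D].mean(axis=1) for e in range(self.n_et)],
                axis=1,
            )
        vals = self._union_values(D)
        out = np.empty((G, self.n_et))
        for e in range(self.n_et):
            out[:, e] = vals[:, self._et_rows[e]].mean(axis=1)
        return out

    def tpe_weighted_performance(self, dosages, b) -> np.ndarray:
        """TPE-weighted performance of a batch of genotypes.

        Equivalent to ``fitness_all_ets(dosages) @ b`` but aggregates the
        ET weights per unique component first, so shared components are
        evaluated once.
        """
        b = np.asarray(b, dtype=float)
        D = _check_dosages(dosages, self.n_loci)
        if self.additive_mode:
            # fold the ET weights into a single per-locus value table
            T = np.tensordot(b, self._additive_tables, axes=(0, 0))
            return T[np.arange(self.n_loci)[None, :], D].mean(axis=1)
        wc = self._incidence @ (b / self.n_loci)
        return self._union_values(D) @ wc

    def to_json(self) -> str:
        """Serialize the architecture (uids + members; values are recomputable)."""
        doc = {
            "master_seed": self.master_seed,
            "k_target": self.k_target,
            "n_et": self.n_et,
            "n_loci": self.n_loci,
            "retain_fraction": self.retain_fraction,
            "submodels": [
                [[int(c.uid), [int(m) for m in c.members]] for c in sm.components]
                for sm in self.submodels
            ],
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, doc: str) -> "ENKModel":
        d = json.loads(doc)
        submodels = [
            NKSubmodel(
                [FitnessComponent(uid, np.array(members)) for uid, members in sm],
                d["n_loci"],
                d["k_target"],
            )
            for sm in d["submodels"]
        ]
        return cls(submodels, d["retain_fraction"], d["master_seed"])


def build_enk_model(
    k_target: int,
    master_seed: int,
    retain_fraction: float = RETAIN_FRACTION_DEFAULT,
    n_et: int = N_ET_DEFAULT,
    n_loci: int = N_LOCI_DEFAULT,
) -> ENKModel:
    """Construct the full E(NK) ensemble.

    The submodel for ET1 is assembled from scratch; each subsequent ET retains
    a uniformly chosen ``retain_fraction`` of the previous ET's components
    unchanged and assembles the remainder anew. At ``K = 1`` the replacement
    components' member loci are a random permutation of the loci vacated by the
    replaced components, preserving the one-gene-one-component bijection within
    every ET.
    """
    if not 0.0 <= retain_fraction <= 1.0:
        raise ConfigurationError("retain_fraction must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(master_seed))
    first = build_nk_submodel(n_loci, k_target, rng)
    submodels = [first]
    n_keep = int(round(retain_fraction * n_loci))
    for _ in range(1, n_et):
        prev = submodels[-1]
        keep = np.zeros(n_loci, dtype=bool)
        keep[rng.choice(n_loci, size=n_keep, replace=False)] = True
        new_idx = np.flatnonzero(~keep)
        comps = list(prev.components)
        if new_idx.size:
            uids = rng.integers(
                0, np.iinfo(np.uint64).max, size=new_idx.size,
                dtype=np.uint64, endpoint=True,
            )
            if k_target == 1:
                vacated = np.array([prev.components[i].members[0] for i in new_idx])
                perm = rng.permutation(vacated)
                for j, i in enumerate(new_idx):
                    comps[i] = FitnessComponent(int(uids[j]), np.array([perm[j]]))
            else:
                sizes = _truncated_poisson(k_target, new_idx.size, rng)
                for j, i in enumerate(new_idx):
                    comps[i] = FitnessComponent(
                        int(uids[j]), rng.choice(n_loci, size=sizes[j], replace=False)
                    )
        submodels.append(NKSubmodel(comps, n_loci, k_target))
    return ENKModel(submodels, retain_fraction, master_seed)


def et_correlation_by_lag(
    model: ENKModel, rng: np.random.Generator, n_genotypes: int = 250
) -> np.ndarray:
    """Mean Pearson correlation of ET-specific fitness by ET lag.

    Draws ``n_genotypes`` random genotypes (dosages Binomial(2, 0.5) per
    locus), computes their fitness in every ET, and averages the pairwise ET
    correlations within each lag class. Returns an array indexed by lag
    ``0 .. n_et - 1`` (lag 0 is identically 1). Zero-variance fitness vectors
    are skipped; a lag class with no valid pair yields NaN.
    """
    if n_genotypes < 3:
        raise ConfigurationError("need at least 3 genotypes")
    D = rng.binomial(2, 0.5, size=(n_genotypes, model.n_loci))
    F = model.fitness_all_ets(D)
    sd = F.std(axis=0)
    sums = np.zeros(model.n_et)
    counts = np.zeros(model.n_et)
    C = np.corrcoef(F, rowvar=False)
    for a in range(model.n_et):
        for b in range(a, model.n_et):
            if sd[a] == 0 or sd[b] == 0:
                continue
            lag = b - a
            sums[lag] += C[a, b]
            counts[lag] += 1
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
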