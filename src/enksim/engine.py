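"""The recurrent hybrid breeding cycle for alternative program structures.

Each breeding program pairs one subpopulation of inbred lines from heterotic
group 1 with one from group 2. Per cycle and program: every line is
testcrossed to five random lines of the opposite group (an incomplete
reciprocal factorial), testcross hybrid performance is the MET-weighted
E(NK) value, and entry-mean noise scaled to a heritability of 0.75 gives the
observed GCA. All intergroup hybrids are predicted by summing parental GCAs;
the top set becomes the experimental hybrids whose true (TPE-weighted) mean
ranks the programs. Lower-ranked programs conduct up to ``p_max`` of their
breeding crosses with lines from higher-ranked programs; parental usage
within a subpopulation follows a Dirichlet draw whose concentrations halve
with every one-fifth rank quantile. Each cross yields one new recombinant
line via three generations of single seed descent plus doubled haploidy, and
the new lines fully replace the previous generation.

Program structures (totals per heterotic group are constant at 500 lines,
125 selected parents, 125 experimental hybrids):

===========  =========  ===========  ========  =================
name         programs   subpop size  selected  exchange cycles
===========  =========  ===========  ========  =================
distributed  5          100          25        every cycle
centralized  1          500          125       (single program)
iso          5          100          25        never
iso7         5          100          25        7, 14, 21, 28
iso21        5          100          25        21
===========  =========  ===========  ========  =================
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from enksim import metrics, seeds
from enksim.environment import (
    TPESchedule,
    sample_met_weights,
    sample_tpe,
)
from enksim.exceptions import ConfigurationError, DegenerateDataError
from enksim.founders import (
    BasePopulationSpec,
    partition_population,
    simulate_base_population,
)
from enksim.genome import GenomeMap, ssd_dh_batch
from enksim.landscape import build_enk_model

P_MAX_DEFAULT = 0.25
#: Total Dirichlet concentration of the per-subpopulation parental
#: contribution draw; calibrated so realized effective parent numbers match
#: the target cycle-averages (~62-65) — see docs/methods.md.
CONTRIBUTION_CONCENTRATION = 600.0


@dataclass(frozen=True)
class StructureConfig:
    """Topology of the breeding operation.

    ``exchange_cycles`` is the set of cycles in which germplasm exchange
    takes place; ``None`` means every cycle.
    """

    name: str
    n_programs: int
    subpop_size: int
    n_selected_parents: int
    n_experimental_hybrids: int
    p_max: float = P_MAX_DEFAULT
    exchange_cycles: frozenset | None = None

    def __post_init__(self):
        if self.n_programs < 1 or self.subpop_size < 2:
            raise ConfigurationError("invalid program topology")
        if not 0 <= self.p_max <= 1:
            raise ConfigurationError("p_max must be in [0, 1]")
        if self.n_selected_parents > self.subpop_size:
            raise ConfigurationError("cannot select more parents than lines")
        if self.n_experimental_hybrids > self.subpop_size**2:
            raise ConfigurationError("cannot select more hybrids than pairs")

    def exchanges_in(self, cycle: int) -> bool:
        if self.n_programs == 1:
            return False
        if self.exchange_cycles is None:
            return True
        return cycle in self.exchange_cycles


def structure_preset(name: str, n_cycles: int = 30, p_max: float = P_MAX_DEFAULT) -> StructureConfig:
    """The five standard structures."""
    if name == "centralized":
        return StructureConfig(name, 1, 500, 125, 125, p_max, frozenset())
    common = dict(n_programs=5, subpop_size=100, n_selected_parents=25,
                  n_experimental_hybrids=25, p_max=p_max)
    if name == "distributed":
        return StructureConfig(name, exchange_cycles=None, **common)
    if name == "iso":
        return StructureConfig(name, exchange_cycles=frozenset(), **common)
    if name == "iso7":
        return StructureConfig(
            name, exchange_cycles=frozenset(range(7, n_cycles + 1, 7)), **common
        )
    if name == "iso21":
        return StructureConfig(name, exchange_cycles=frozenset({21}), **common)
    raise ConfigurationError(f"unknown structure {name!r}")


@dataclass(frozen=True)
class SimulationConfig:
    """Run-level settings shared by all structures."""

    k_target: int
    scenario: str = "gradual"
    n_cycles: int = 30
    n_reps: int = 20
    h2: float = 0.75
    n_testers: int = 5
    master_seed: int = 0
    n_et: int = 12
    n_loci: int = 500
    concentration_scale: float = CONTRIBUTION_CONCENTRATION
    kernel_width: float | None = None
    tpe_concentration: float | None = None
    gca_corr_every: int = 3
    pct_gca_max_lines: int = 100

    def __post_init__(self):
        if not 0 < self.h2 <= 1:
            raise ConfigurationError("h2 must be in (0, 1]")
        if self.n_testers < 1:
            raise ConfigurationError("n_testers must be >= 1")
        if self.n_reps < 1 or self.n_cycles < 1:
            raise ConfigurationError("n_reps and n_cycles must be >= 1")

    def schedule(self) -> TPESchedule:
        kwargs = {}
        if self.kernel_width is not None:
            kwargs["kernel_width"] = self.kernel_width
        if self.tpe_concentration is not None:
            kwargs["concentration"] = self.tpe_concentration
        return TPESchedule(self.scenario, self.n_cycles, n_et=self.n_et, **kwargs)


# ---------------------------------------------------------------------------
# cycle operations
# ---------------------------------------------------------------------------

@dataclass
class GCAResult:
    true_means: np.ndarray  # (S,)
    tester_idx: np.ndarray  # (S, T) indices into the partner subpopulation
    hybrid_values: np.ndarray  # (S, T) true MET-weighted testcross values


def evaluate_gca(lines, partner, model, met_weights, n_testers, rng) -> GCAResult:
    """Testcross GCA evaluation of ``lines`` against random partner testers.

    Testers are drawn uniformly without replacement from the partner
    subpopulation, independently per line. Testcross hybrid values are the
    MET-weighted E(NK) performance of the F1 dosage; each line's true mean is
    the average over its testers.
    """
    S, n = lines.shape
    P = partner.shape[0]
    if n_testers > P:
        raise ConfigurationError("more testers requested than partner lines")
    keys = rng.random((S, P))
    tester_idx = np.argpartition(keys, n_testers - 1, axis=1)[:, :n_testers]
    hyb = (
        lines[:, None, :].astype(np.int64) + partner[tester_idx].astype(np.int64)
    ).reshape(S * n_testers, n)
    vals = model.tpe_weighted_performance(hyb, met_weights).reshape(S, n_testers)
    return GCAResult(vals.mean(axis=1), tester_idx, vals)


def add_entry_mean_noise(true_means, h2, rng) -> np.ndarray:
    """Observed GCA: true mean plus noise scaled to entry-mean heritability h2."""
    t = np.asarray(true_means, dtype=float)
    if h2 >= 1.0 or t.size < 2 or np.ptp(t) == 0.0:
        return t.copy()
    var = t.var(ddof=1)
    sigma = np.sqrt(var * (1.0 - h2) / h2)
    return t + rng.normal(0.0, sigma, size=t.size)


def predict_and_select_hybrids(gca1, gca2, n_select):
    """Top hybrids by predicted (GCA-sum) value.

    Returns (idx1, idx2) of the selected pairs, best first; exact ties are
    broken lexicographically by parent index.
    """
    g1 = np.asarray(gca1, dtype=float)
    g2 = np.asarray(gca2, dtype=float)
    if g1.size == 0 or g2.size == 0:
        raise ConfigurationError("empty subpopulation")
    if n_select > g1.size * g2.size:
        raise ConfigurationError("n_select exceeds the number of hybrid pairs")
    pred = (g1[:, None] + g2[None, :]).ravel()
    i = np.repeat(np.arange(g1.size), g2.size)
    j = np.tile(np.arange(g2.size), g1.size)
    order = np.lexsort((j, i, -pred))[:n_select]
    return i[order], j[order]


def program_performance(selected_hybrid_values) -> float:
    """Mean true performance of a program's selected experimental hybrids."""
    v = np.asarray(selected_hybrid_values, dtype=float)
    if v.size == 0:
        raise ConfigurationError("no experimental hybrids")
    return float(v.mean())


def top_hybrid(hybrid_values_by_program) -> float:
    """Best single experimental hybrid across all programs."""
    vals = [np.asarray(v, dtype=float) for v in hybrid_values_by_program]
    if not vals or any(v.size == 0 for v in vals):
        raise ConfigurationError("no experimental hybrids")
    return float(max(v.max() for v in vals))


def rank_programs(performances) -> np.ndarray:
    """Programs in descending performance order; ties broken by index."""
    perf = np.asarray(performances, dtype=float)
    return np.lexsort((np.arange(perf.size), -perf))


def external_proportions(ranked_performances, p_max):
    """External-cross totals and donor shares for ranked programs.

    ``ranked_performances`` must be sorted descending (rank 0 = best).
    Returns ``(x, shares)`` where ``x[r] = p_max * r / (R - 1)`` is the total
    external fraction of the rank-``r`` program and ``shares[r, q]`` (q < r)
    its share from the rank-``q`` donor, proportional to the performance gap
    and summing to ``x[r]`` (equal split when all gaps are zero).
    """
    perf = np.asarray(ranked_performances, dtype=float)
    R = perf.size
    x = np.zeros(R)
    shares = np.zeros((R, R))
    if R == 1:
        return x, shares
    for r in range(1, R):
        x[r] = p_max * r / (R - 1)
        gaps = perf[:r] - perf[r]
        total = gaps.sum()
        if total > 0:
            shares[r, :r] = x[r] * gaps / total
        else:
            shares[r, :r] = x[r] / r
    return x, shares


def individual_contributions(ranks, n_selected, concentration_scale, rng) -> np.ndarray:
    """Per-line contribution values within one subpopulation.

    ``ranks`` are 1-based within-subpopulation ranks (1 = best observed GCA).
    Lines ranked beyond ``n_selected`` contribute zero; the selected lines'
    contributions are one Dirichlet draw whose concentration weights halve
    with every one-fifth rank quantile, scaled to ``concentration_scale``.
    """
    r = np.asarray(ranks)
    if n_selected > r.size:
        raise ConfigurationError("n_selected exceeds subpopulation size")
    sel = r <= n_selected
    w = 2.0 ** (-(r[sel] - 1) / (n_selected / 5.0))
    alpha = concentration_scale * w / w.sum()
    out = np.zeros(r.size)
    out[sel] = rng.dirichlet(alpha)
    return out


def sample_breeding_crosses(
    internal_contribs, x_r, donor_programs, donor_shares, donor_contribs,
    n_crosses, rng,
):
    """Parent pairs for one subpopulation's breeding crosses.

    Each cross is independently designated external with probability ``x_r``.
    An external cross pairs an internal parent (sampled by internal
    contributions) with a donor-program parent (program by share, line by that
    program's contributions); an internal cross samples two internal parents
    by contributions, resampling the second until it differs from the first.
    Repeated identical pairs are allowed; selfing is excluded.

    Returns ``(prog_a, idx_a, prog_b, idx_b)`` with program index ``-1``
    denoting the internal subpopulation.
    """
    p_int = np.asarray(internal_contribs, dtype=float)
    if (p_int > 0).sum() < 2:
        raise ConfigurationError(
            "need at least two usable internal parents to exclude selfing"
        )
    ext = rng.random(n_crosses) < x_r
    first = rng.choice(p_int.size, size=n_crosses, p=p_int)
    prog_b = np.full(n_crosses, -1, dtype=np.int64)
    idx_b = np.zeros(n_crosses, dtype=np.int64)

    internal = np.flatnonzero(~ext)
    if internal.size:
        sec = rng.choice(p_int.size, size=internal.size, p=p_int)
        clash = sec == first[internal]
        while clash.any():
            sec[clash] = rng.choice(p_int.size, size=int(clash.sum()), p=p_int)
            clash = sec == first[internal]
        idx_b[internal] = sec

    external = np.flatnonzero(ext)
    if external.size:
        sh = np.asarray(donor_shares, dtype=float)
        probs = sh / sh.sum()
        dsel = rng.choice(len(donor_programs), size=external.size, p=probs)
        for k, (dprog, contrib) in enumerate(zip(donor_programs, donor_contribs)):
            m = dsel == k
            if m.any():
                prog_b[external[m]] = dprog
                idx_b[external[m]] = rng.choice(
                    len(contrib), size=int(m.sum()), p=np.asarray(contrib, float)
                )
    prog_a = np.full(n_crosses, -1, dtype=np.int64)
    return prog_a, first, prog_b, idx_b


def effective_parent_number(slot_counts) -> float:
    """Inverse Simpson index of realized parent-slot proportions."""
    c = np.asarray(slot_counts, dtype=float)
    total = c.sum()
    if total <= 0:
        raise DegenerateDataError("no parent slots")
    b = c / total
    return float(1.0 / np.dot(b, b))


# ---------------------------------------------------------------------------
# full simulation
# ---------------------------------------------------------------------------

@dataclass
class CycleRecord:
    """Per-cycle outputs of one replicate."""

    cycle: int
    true_tpe: np.ndarray
    met_weights: np.ndarray  # (R, n_et)
    program_performance: np.ndarray  # (R,) mean true experimental-hybrid value
    rank_order: np.ndarray  # programs, best first
    external_total: np.ndarray  # (R,) per program
    top_hybrid: float
    effective_parents: float
    pct_gca: float
    gca_corr: float
    fst: float
    uw: float
    ne: float


def _ranks_from_observed(observed) -> np.ndarray:
    order = np.lexsort((np.arange(observed.size), -observed))
    ranks = np.empty(observed.size, dtype=np.int64)
    ranks[order] = np.arange(1, observed.size + 1)
    return ranks


class _ReplicateState:
    """Populations and trajectories of one replicate of one structure."""

    def __init__(self, structure: StructureConfig, sim: SimulationConfig, rep: int,
                 base_spec: BasePopulationSpec | None = None):
        self.structure = structure
        self.sim = sim
        self.rep = rep
        if sim.n_loci % 10 == 0:
            self.gmap = GenomeMap(n_chromosomes=10, n_loci_per_chrom=sim.n_loci // 10)
        else:
            self.gmap = GenomeMap(n_chromosomes=1, n_loci_per_chrom=sim.n_loci)
        self.model = build_enk_model(
            sim.k_target,
            master_seed=seeds.subseed(sim.master_seed, rep, seeds.LANDSCAPE),
            n_et=sim.n_et,
            n_loci=sim.n_loci,
        )
        self.schedule = sim.schedule()
        spec = base_spec or BasePopulationSpec(
            n_lines=2 * structure.n_programs * structure.subpop_size
        )
        founders = simulate_base_population(
            spec, self.gmap, seeds.substream(sim.master_seed, rep, seeds.FOUNDERS)
        )
        part = partition_population(
            spec.n_lines,
            structure.n_programs,
            seeds.substream(sim.master_seed, rep, seeds.PARTITION, structure.n_programs),
        )
        # pops[(program, group)] -> (subpop_size, n_loci) homozygous haplotypes
        self.pops = {
            (p, g): founders[part.members(g, p)]
            for p in range(structure.n_programs)
            for g in (1, 2)
        }
        # pooled allele-frequency trajectory per heterotic group, grown each
        # cycle; the per-cycle Ne is a constant-size fit to the whole of it
        self.freq_traj = {g: [self._pooled_freq(g)] for g in (1, 2)}

    def _pooled_freq(self, group: int) -> np.ndarray:
        mats = [self.pops[(p, group)] for p in range(self.structure.n_programs)]
        return np.concatenate(mats, axis=0).mean(axis=0)


def run_cycle(state: _ReplicateState, cycle: int) -> CycleRecord:
    st, sim = state.structure, state.sim
    ms, rep = sim.master_seed, state.rep
    R = st.n_programs
    model = state.model

    b_true = sample_tpe(state.schedule, cycle, seeds.substream(ms, rep, seeds.TPE, cycle))
    met = np.stack([
        sample_met_weights(b_true, seeds.substream(ms, rep, seeds.MET, cycle, p))
        for p in range(R)
    ])

    gca: dict[tuple[int, int], GCAResult] = {}
    obs: dict[tuple[int, int], np.ndarray] = {}
    for p in range(R):
        for g in (1, 2):
            res = evaluate_gca(
                state.pops[(p, g)], state.pops[(p, 3 - g)], model, met[p],
                sim.n_testers, seeds.substream(ms, rep, seeds.TESTERS, cycle, p, g),
            )
            gca[(p, g)] = res
            obs[(p, g)] = add_entry_mean_noise(
                res.true_means, sim.h2,
                seeds.substream(ms, rep, seeds.NOISE, cycle, p, g),
            )

    # hybrid prediction, selection, program performance
    perf = np.empty(R)
    hybrid_vals = []
    for p in range(R):
        i1, i2 = predict_and_select_hybrids(
            obs[(p, 1)], obs[(p, 2)], st.n_experimental_hybrids
        )
        D = (
            state.pops[(p, 1)][i1].astype(np.int64)
            + state.pops[(p, 2)][i2].astype(np.int64)
        )
        true_vals = model.tpe_weighted_performance(D, b_true)
        hybrid_vals.append(true_vals)
        perf[p] = program_performance(true_vals)
    top = top_hybrid(hybrid_vals)

    rank_order = rank_programs(perf)
    if st.exchanges_in(cycle):
        x_rank, shares_rank = external_proportions(perf[rank_order], st.p_max)
    else:
        x_rank = np.zeros(R)
        shares_rank = np.zeros((R, R))
    x_prog = np.zeros(R)
    x_prog[rank_order] = x_rank

    # contributions and crosses (per program per heterotic group)
    contribs = {
        (p, g): individual_contributions(
            _ranks_from_observed(obs[(p, g)]), st.n_selected_parents,
            sim.concentration_scale,
            seeds.substream(ms, rep, seeds.CONTRIB, cycle, p, g),
        )
        for p in range(R) for g in (1, 2)
    }
    crosses = {}
    slot_counts_g1 = np.zeros((R, st.subpop_size))
    for p in range(R):
        r = int(np.flatnonzero(rank_order == p)[0])
        donor_programs = [int(rank_order[q]) for q in range(r)]
        for g in (1, 2):
            donor_contribs = [contribs[(dp, g)] for dp in donor_programs]
            pa, ia, pb, ib = sample_breeding_crosses(
                contribs[(p, g)], x_rank[r], donor_programs,
                shares_rank[r, :r] if r else np.zeros(0), donor_contribs,
                st.subpop_size,
                seeds.substream(ms, rep, seeds.CROSSES, cycle, p, g),
            )
            crosses[(p, g)] = (pa, ia, pb, ib)
            if g == 1:
                for prog, idx in ((pa, ia), (pb, ib)):
                    owner = np.where(prog < 0, p, prog)
                    np.add.at(slot_counts_g1, (owner, idx), 1.0)
    eff_parents = effective_parent_number(slot_counts_g1.ravel())

    rec = CycleRecord(
        cycle=cycle,
        true_tpe=b_true,
        met_weights=met,
        program_performance=perf,
        rank_order=rank_order,
        external_total=x_prog,
        top_hybrid=top,
        effective_parents=eff_parents,
        pct_gca=_cycle_pct_gca(state, gca, cycle),
        gca_corr=_cycle_gca_corr(state, obs, met, cycle),
        fst=_cycle_fst(state),
        uw=_cycle_uw(state),
        ne=_cycle_ne(state),
    )

    # advance both heterotic groups: complete generational replacement
    new_pops = {}
    for p in range(R):
        for g in (1, 2):
            pa, ia, pb, ib = crosses[(p, g)]
            hap_a = np.empty((st.subpop_size, sim.n_loci), dtype=np.uint8)
            hap_b = np.empty_like(hap_a)
            for slot, (prog, idx), hap in (
                (0, (pa, ia), hap_a), (1, (pb, ib), hap_b)
            ):
                for dp in np.unique(prog):
                    m = prog == dp
                    src = p if dp < 0 else int(dp)
                    hap[m] = state.pops[(src, g)][idx[m]]
            new_pops[(p, g)] = ssd_dh_batch(
                hap_a, hap_b, state.gmap,
                seeds.substream(ms, rep, seeds.ADVANCE, cycle, p, g),
            )
    state.pops = new_pops
    for g in (1, 2):
        state.freq_traj[g].append(state._pooled_freq(g))
    return rec


def _cycle_pct_gca(state, gca, cycle) -> float:
    st, sim = state.structure, state.sim
    rng = seeds.substream(sim.master_seed, state.rep, seeds.PCTGCA, cycle)
    vals = []
    for p in range(st.n_programs):
        p1, p2, y = [], [], []
        for g in (1, 2):
            res = gca[(p, g)]
            S, T = res.hybrid_values.shape
            rows = np.arange(S)
            if S > sim.pct_gca_max_lines:
                rows = rng.choice(S, size=sim.pct_gca_max_lines, replace=False)
            own = np.repeat(rows, T)
            testers = res.tester_idx[rows].ravel()
            if g == 1:
                p1.append(own)
                p2.append(testers)
            else:
                p1.append(testers)
                p2.append(own)
            y.append(res.hybrid_values[rows].ravel())
        try:
            vals.append(
                metrics.pct_gca(np.concatenate(p1), np.concatenate(p2), np.concatenate(y))
            )
        except DegenerateDataError:
            continue
    return float(np.mean(vals)) if vals else np.nan


def _cycle_gca_corr(state, obs, met, cycle) -> float:
    st, sim = state.structure, state.sim
    if st.n_programs < 2 or cycle % sim.gca_corr_every != 0:
        return np.nan
    rng = seeds.substream(sim.master_seed, state.rep, seeds.GCACORR, cycle)
    foreign = evaluate_gca(
        state.pops[(0, 1)], state.pops[(1, 2)], state.model, met[0],
        sim.n_testers, rng,
    )
    try:
        return metrics.gca_correlation(obs[(0, 1)], foreign.true_means)
    except DegenerateDataError:
        return np.nan


def _cycle_fst(state) -> float:
    if state.structure.n_programs < 2:
        return np.nan
    vals = []
    for g in (1, 2):
        mats = [
            2 * state.pops[(p, g)].astype(np.int64)
            for p in range(state.structure.n_programs)
        ]
        try:
            vals.append(metrics.fst_global(mats))
        except DegenerateDataError:
            continue
    return float(np.mean(vals)) if vals else np.nan


def _cycle_uw(state) -> float:
    vals = [
        metrics.uw_proportion(2 * state.pops[(p, g)].astype(np.int64))
        for p in range(state.structure.n_programs)
        for g in (1, 2)
    ]
    return float(np.mean(vals))


def _cycle_ne(state) -> float:
    """Constant-Ne fit to the pooled trajectory of generations 1..current."""
    vals = []
    for g in (1, 2):
        traj = state.freq_traj[g]
        if len(traj) < 2:
            return np.nan
        try:
            vals.append(metrics.effective_population_size(np.stack(traj)))
        except DegenerateDataError:
            continue
    return float(np.mean(vals)) if vals else np.nan


def run_replicate(
    structure: StructureConfig, sim: SimulationConfig, rep: int
) -> list[CycleRecord]:
    """Run all cycles of one replicate; records are per cycle."""
    state = _ReplicateState(structure, sim, rep)
    records = []
    for cycle in range(1, sim.n_cycles + 1):
        records.append(run_cycle(state, cycle))
    return records


def run_simulation(
    structure: StructureConfig, sim: SimulationConfig, reps=None
) -> list[list[CycleRecord]]:
    """Run the configured replicates (default ``range(n_reps)``)."""
    if reps is None:
        reps = range(sim.n_reps)
    return [run_replicate(structure, sim, rep) for rep in reps]


def records_to_frame(records_by_rep, structure: StructureConfig,
                     sim: SimulationConfig) -> pd.DataFrame:
    """Tidy per-cycle metric table (one row per rep, cycle, metric, program)."""
    rows = []
    for rep, records in enumerate(records_by_rep):
        for rec in records:
            base = dict(rep=rep, cycle=rec.cycle, structure=structure.name,
                        K=sim.k_target, scenario=sim.scenario)
            for p in range(structure.n_programs):
                rows.append(dict(base, metric="program_performance", program=p,
                                 value=rec.program_performance[p]))
                rows.append(dict(base, metric="external_total", program=p,
                                 value=rec.external_total[p]))
            for name in ("top_hybrid", "effective_parents", "pct_gca",
                         "gca_corr", "fst", "uw", "ne"):
                rows.append(dict(base, metric=name, program=-1,
                                 value=getattr(rec, name)))
    return pd.DataFrame(rows)


def simulate_effective_parents(
    rng,
    n_subpops: int = 5,
    subpop_size: int = 100,
    n_selected: int = 25,
    concentration_scale: float = CONTRIBUTION_CONCENTRATION,
    n_crosses: int | None = None,
    n_cycles: int = 30,
) -> float:
    """Cycle-averaged effective parent number of isolated subpopulations.

    Standalone contribution simulation (no genetics): per cycle each
    subpopulation draws Dirichlet contributions for its selected parents and
    samples ``n_crosses`` no-self crosses; the inverse Simpson index of the
    realized parent-slot proportions across subpopulations is averaged over
    cycles.
    """
    if n_crosses is None:
        n_crosses = subpop_size
    out = []
    for _ in range(n_cycles):
        slot_counts = np.zeros((n_subpops, subpop_size))
        for s in range(n_subpops):
            ranks = np.arange(1, subpop_size + 1)
            contrib = individual_contributions(
                ranks, n_selected, concentration_scale, rng
            )
            _, ia, _, ib = sample_breeding_crosses(
                contrib, 0.0, [], np.zeros(0), [], n_crosses, rng
            )
            np.add.at(slot_counts[s], ia, 1.0)
            np.add.at(slot_counts[s], ib, 1.0)
        out.append(effective_parent_number(slot_counts.ravel()))
    return float(np.mean(out))
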