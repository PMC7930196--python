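"""Synthetic tip-dated mitogenome samples with known ground truth.

Two generators:

* **genealogy mode** — the persistent-ancestor scenario: a single ancestral
  lineage of age T gives rise to modern tips.  A configurable fraction of
  tips are exact, unmutated copies of the ancestor (the lineage persisted to
  the present); the rest branch off the ancestral line and accumulate
  private Poisson mutations.  Branch times are either all equal to T
  (``star``; tip counts are exactly Poisson(mu*L*T)) or uniform on (0, T)
  (``uniform``; lineages sprout from the persistent ancestor throughout its
  lifetime, which is what makes plain rho dating underestimate T).

* **coalescent mode** — a serial-sample haploid coalescent under a
  piecewise-exponential female effective-size history (msprime), with
  Poisson mutations scattered on branches.  Clade labels derived from the
  root's child subtrees stand in for haplogroups.

Sampling ages are years BP (present = 1950); moderns collected 2000 AD sit
at -50 BP.  All randomness flows from ``SimulationConfig.seed``: identical
configs give identical output, including byte-identical written fixtures.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Literal, Sequence

import msprime
import numpy as np

from .sequence_model import (
    MODERN_AGE_BP,
    MT_LENGTH,
    MitoProfile,
    VariantCall,
    format_variant_token,
    infer_macrohaplogroup,
    load_reference,
    parse_variant_token,
    profile_to_sequence,
    write_metadata,
)

_BASES = "ACGT"
_MACRO_CYCLE = ("M", "N", "R")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic generators.

    Defaults emulate the empirical setting: full 16,569-bp mitogenomes, a
    per-site per-year mutation rate of 1.6e-8 (the midpoint of recent
    germline estimates), 25-year generations, a female effective size of
    5,000 through most of prehistory with exponential growth to 50,000 over
    the last two millennia, and sampling tiers spanning moderns (-50 BP) to
    ~45,000 BP.
    """

    L: int = MT_LENGTH
    mu_site: float = 1.6e-8
    generation_years: float = 25.0
    #: (time BP, effective size) breakpoints, present first; sizes are
    #: interpolated exponentially between breakpoints and constant beyond the
    #: oldest one.
    demography: tuple[tuple[float, float], ...] = (
        (0.0, 50_000.0),
        (2_000.0, 5_000.0),
        (50_000.0, 5_000.0),
    )
    #: (age BP, number of samples) tiers.
    sampling: tuple[tuple[float, int], ...] = (
        (MODERN_AGE_BP, 100),
        (1_000.0, 20),
        (5_000.0, 20),
        (15_000.0, 20),
        (30_000.0, 20),
        (45_000.0, 10),
    )
    persistent_fraction: float = 0.0
    branch_time_mode: Literal["star", "uniform"] = "star"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if self.mu_site < 0:
            raise ValueError("mu_site must be non-negative")
        if self.generation_years <= 0:
            raise ValueError("generation_years must be positive")
        for t, n in self.demography:
            if n < 1:
                raise ValueError(f"demography size {n} at {t} BP must be >= 1")
        for age, n in self.sampling:
            if age < -70:
                raise ValueError(f"sampling age {age} BP < -70")
            if n < 1:
                raise ValueError("each sampling tier needs n >= 1")
        if not 0.0 <= self.persistent_fraction <= 1.0:
            raise ValueError("persistent_fraction must be in [0, 1]")
        if self.branch_time_mode not in ("star", "uniform"):
            raise ValueError("branch_time_mode must be 'star' or 'uniform'")

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _age_to_generations(age_bp: float, generation_years: float) -> float:
    """Convert years BP to coalescent generations before the modern tier."""
    return (age_bp - MODERN_AGE_BP) / generation_years


def _draw_alt(rng: np.random.Generator, ref_base: str) -> str:
    choices = [b for b in _BASES if b != ref_base]
    return choices[int(rng.integers(3))]


# ---------------------------------------------------------------------------
# genealogy mode


def simulate_genealogy_mode(
    config: SimulationConfig, seed: int | None = None, reference: str | None = None
) -> tuple[list[MitoProfile], dict[str, Any]]:
    """Persistent-ancestor scenario: one dated ancestor plus modern tips.

    Requires exactly two sampling tiers: one ancient (the ancestral age T,
    sample count ignored — one ancestor is emitted) and one modern.  Each
    modern tip is an exact copy of the ancestor with probability
    ``persistent_fraction``; otherwise it branches off the ancestral line at
    branch time b (= T in ``star`` mode, ~Uniform(0, T) in ``uniform`` mode)
    and carries K ~ Poisson(mu_site * L * b) private substitutions at fresh,
    previously unused positions, so pairwise counts are collision-free.
    """
    ancient_tiers = [(a, n) for a, n in config.sampling if a > 0]
    modern_tiers = [(a, n) for a, n in config.sampling if a <= 0]
    if len(ancient_tiers) != 1 or len(modern_tiers) != 1:
        raise ValueError("genealogy mode needs exactly one ancient and one modern sampling tier")
    T = ancient_tiers[0][0]
    n_modern = modern_tiers[0][1]
    modern_age = modern_tiers[0][0]

    rng = np.random.default_rng(config.seed if seed is None else seed)
    ref = load_reference() if reference is None else reference
    position_pool = rng.permutation(np.arange(1, config.L + 1))
    next_free = 0

    ancestor = MitoProfile(
        id="anc", age_bp=T, haplogroup="R", macrohaplogroup="R", variants=frozenset()
    )
    profiles = [ancestor]
    per_tip = []
    for i in range(n_modern):
        persistent = bool(rng.random() < config.persistent_fraction)
        if persistent:
            branch_time, k = 0.0, 0
        else:
            branch_time = T if config.branch_time_mode == "star" else float(rng.uniform(0.0, T))
            k = int(rng.poisson(config.mu_site * config.L * branch_time))
        if next_free + k > config.L:
            raise ValueError("more mutations demanded than free sites in the mitogenome")
        variants = []
        for pos in position_pool[next_free : next_free + k]:
            pos = int(pos)
            variants.append(
                VariantCall(pos, "substitution", ref[pos - 1], _draw_alt(rng, ref[pos - 1]))
            )
        next_free += k
        profiles.append(
            MitoProfile(
                id=f"mod{i}",
                age_bp=modern_age,
                haplogroup="R",
                macrohaplogroup="R",
                variants=frozenset(variants),
            )
        )
        per_tip.append(
            {"id": f"mod{i}", "k": k, "persistent": persistent, "branch_time": branch_time}
        )

    truth = {
        "mode": "genealogy",
        "T": T,
        "mu_site": config.mu_site,
        "per_tip": per_tip,
        "root_variants": {"R": []},
        "seed": int(config.seed if seed is None else seed),
        "config_hash": config.hash(),
    }
    return profiles, truth


# ---------------------------------------------------------------------------
# coalescent mode


def _build_demography(config: SimulationConfig) -> msprime.Demography:
    bps = sorted(config.demography, key=lambda p: p[0])
    times = [max(0.0, _age_to_generations(t, config.generation_years)) for t, _ in bps]
    sizes = [n for _, n in bps]

    def growth(i: int) -> float:
        if i + 1 >= len(bps) or times[i + 1] <= times[i]:
            return 0.0
        return float(np.log(sizes[i] / sizes[i + 1]) / (times[i + 1] - times[i]))

    dem = msprime.Demography()
    dem.add_population(name="pop0", initial_size=sizes[0], growth_rate=growth(0))
    for i in range(1, len(bps)):
        dem.add_population_parameters_change(
            time=times[i], initial_size=sizes[i], growth_rate=growth(i), population="pop0"
        )
    return dem


def simulate_coalescent_mode(
    config: SimulationConfig, seed: int | None = None, reference: str | None = None
) -> tuple[list[MitoProfile], dict[str, Any]]:
    """Serial-sample haploid coalescent with Poisson mutations on branches.

    Mutation events pick a uniform position and set it to a uniform non-
    reference base; a tip's haplotype is the last event per position on its
    root-to-tip path, so recurrent hits at one position collapse (a slight,
    documented undercount mirroring real recurrent mutation).  Each child
    subtree of the genealogy root becomes a labelled clade (haplogroup
    stand-in) whose root haplotype is recorded in the truth record.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    ref = load_reference() if reference is None else reference

    samples = [
        msprime.SampleSet(
            n, time=_age_to_generations(age, config.generation_years), population="pop0"
        )
        for age, n in config.sampling
    ]
    ts = msprime.sim_ancestry(
        samples=samples,
        demography=_build_demography(config),
        ploidy=1,
        random_seed=int(rng.integers(1, 2**31 - 1)),
    )
    tree = ts.first()
    if tree.num_roots != 1:
        raise RuntimeError("genealogy did not fully coalesce")
    root = tree.root

    # Poisson mutation events per branch, in years.
    events: dict[int, list[tuple[int, str]]] = {}
    for node in tree.nodes():
        if node == root:
            continue
        branch_years = tree.branch_length(node) * config.generation_years
        n_mut = int(rng.poisson(branch_years * config.mu_site * config.L))
        node_events = []
        for _ in range(n_mut):
            pos = int(rng.integers(1, config.L + 1))
            node_events.append((pos, _draw_alt(rng, ref[pos - 1])))
        events[node] = node_events

    def path_state(node: int) -> dict[int, str]:
        """Allele state accumulated root -> node, last event per position wins."""
        path = []
        u = node
        while u != root:
            path.append(u)
            u = tree.parent(u)
        state: dict[int, str] = {}
        for u in reversed(path):  # root-most branch first
            for pos, alt in events.get(u, []):
                state[pos] = alt
        return state

    # clades = child subtrees of the root
    clade_of: dict[int, int] = {}
    clade_labels: dict[int, str] = {}
    clade_root_variants: dict[str, frozenset[VariantCall]] = {}
    clade_heads = tree.children(root) or (root,)  # single-tip degenerate case
    for i, child in enumerate(clade_heads):
        macro = _MACRO_CYCLE[i % 3]
        label = f"{macro}{i // 3 + 1}"
        clade_labels[child] = label
        for u in tree.nodes(child):
            clade_of[u] = child
        clade_root_variants[label] = frozenset(
            VariantCall(pos, "substitution", ref[pos - 1], alt)
            for pos, alt in path_state(child).items()
        )

    profiles = []
    sample_truth = []
    for sample_node in ts.samples():
        node_time = tree.time(sample_node)
        age_bp = node_time * config.generation_years + MODERN_AGE_BP
        label = clade_labels[clade_of[sample_node]]
        variants = frozenset(
            VariantCall(pos, "substitution", ref[pos - 1], alt)
            for pos, alt in path_state(sample_node).items()
        )
        profiles.append(
            MitoProfile(
                id=f"s{sample_node}",
                age_bp=float(age_bp),
                haplogroup=label,
                macrohaplogroup=infer_macrohaplogroup(label),
                variants=variants,
            )
        )
        sample_truth.append({"id": f"s{sample_node}", "age_bp": float(age_bp), "clade": label})

    truth = {
        "mode": "coalescent",
        "tmrca_generations": float(tree.time(root)),
        "tmrca_years_bp": float(tree.time(root) * config.generation_years + MODERN_AGE_BP),
        "samples": sample_truth,
        "root_variants": {
            label: sorted(format_variant_token(v) for v in vs)
            for label, vs in clade_root_variants.items()
        },
        "mu_site": config.mu_site,
        "seed": int(config.seed if seed is None else seed),
        "config_hash": config.hash(),
    }
    return profiles, truth


def root_variants_from_truth(
    truth: dict[str, Any], reference: str | None = None
) -> dict[str, frozenset[VariantCall]]:
    """Rebuild per-clade root haplotypes from a truth record."""
    ref = load_reference() if reference is None else reference
    return {
        label: frozenset(parse_variant_token(t, ref) for t in tokens)
        for label, tokens in truth["root_variants"].items()
    }


# ---------------------------------------------------------------------------
# fixture writing


def write_fixture(
    profiles: Sequence[MitoProfile],
    truth: dict[str, Any],
    out_dir: str | Path,
    reference: str | None = None,
) -> dict[str, Path]:
    """Write aligned FASTA, metadata CSV, clade-roots table and truth JSON.

    Files round-trip through the sequence_model readers; the truth JSON
    carries the seed and config hash for provenance.
    """
    if not profiles:
        raise ValueError("no profiles to write")
    ref = load_reference() if reference is None else reference
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "samples.fasta",
        "metadata": out / "metadata.csv",
        "roots": out / "roots.tsv",
        "truth": out / "truth.json",
    }
    with open(paths["fasta"], "w") as fh:
        for p in profiles:
            fh.write(f">{p.id}\n")
            seq = profile_to_sequence(p, ref)
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    write_metadata(profiles, paths["metadata"])
    with open(paths["roots"], "w") as fh:
        for label, tokens in sorted(truth.get("root_variants", {}).items()):
            fh.write(f"{label}\t{' '.join(tokens)}\n")
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths
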