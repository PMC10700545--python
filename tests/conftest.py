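import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from penguin import contacts as ct
from penguin import epin as ep
from penguin import io as pio
from penguin.config import RunConfig
from penguin.simulate import SimulationConfig, make_fixture_bundle


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A 30-promoter synthetic bundle shared across test modules."""
    out = tmp_path_factory.mktemp("bundle")
    manifest = make_fixture_bundle(SimulationConfig(seed=11, n_genes=30), out)
    return manifest


@pytest.fixture(scope="session")
def small_contacts(small_bundle):
    """Classified, filtered, normalized and prioritized contacts."""
    paths = small_bundle["paths"]
    loops = pio.read_loops(paths["loops"])
    genes = pio.read_gene_models(paths["gene_models"])
    peaks = pio.read_bed_intervals(paths["enhancer_peaks"])
    contacts = ct.filter_short_range(ct.classify_ep_contacts(loops, genes, peaks))
    ct.attach_counts(contacts, pio.read_pair_counts(paths["pair_counts"]))
    decay = ct.fit_distance_decay(contacts)
    for c in contacts:
        ct.normalize_contact(c, decay)
        ct.prioritize_bins(c)
    return contacts


@pytest.fixture(scope="session")
def small_epins(small_bundle, small_contacts):
    paths = small_bundle["paths"]
    hits = pio.read_fimo_hits(paths["motif_hits"])
    edges = pio.read_ppi_table(paths["ppi"])
    expr = pio.read_expression(paths["expression"])
    graph = ep.filter_ppi_context(edges, expr)
    epins = ep.epins_from_contacts(small_contacts, hits, graph)
    for e in epins:
        e.validate()
    return epins


def brute_force_betweenness(edges):
    """Independent all-pairs shortest-path betweenness (unnormalized, even
    splitting over equally short paths), via BFS path counting."""
    adj = {}
    for a, b in edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    nodes = sorted(adj)
    btw = {v: 0.0 for v in nodes}
    for si, s in enumerate(nodes):
        for t in nodes[si + 1:]:
            # enumerate all shortest s-t paths
            dist = {s: 0}
            sigma = {s: 1}
            preds = {s: []}
            frontier = [s]
            while frontier:
                nxt = []
                for u in frontier:
                    for w in adj[u]:
                        if w not in dist:
                            dist[w] = dist[u] + 1
                            sigma[w] = 0
                            preds[w] = []
                            nxt.append(w)
                        if dist[w] == dist[u] + 1:
                            sigma[w] += sigma[u]
                            preds[w].append(u)
                frontier = nxt
            if t not in dist:
                continue
            # sigma(s,t | v) = sigma(s,v) * sigma(v,t); count sigma(v,t)
            # by dynamic programming over the BFS DAG, deepest first
            sigma_to_t = {t: 1}
            order = sorted(((d, v) for v, d in dist.items() if d < dist[t]), reverse=True)
            for _d, v in order:
                sigma_to_t[v] = sum(
                    sigma_to_t.get(w, 0)
                    for w in adj[v]
                    if dist.get(w) == dist[v] + 1
                )
            for v in nodes:
                if v in (s, t) or v not in dist or not (0 < dist[v] < dist[t]):
                    continue
                n_through = sigma[v] * sigma_to_t.get(v, 0)
                if n_through:
                    btw[v] += n_through / sigma[t]
    return btw
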