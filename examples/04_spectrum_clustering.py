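"""Characterize and cluster networks by their Laplacian spectra.

Generates three synthetic families with distinct spectral signatures —
nearly-bipartite (eigenvalue mass near 2), motif-duplication grown
(mass near 1) and community-structured (mass near 0) — computes the
pairwise Earth Mover's distance between their 200-bin normalized-Laplacian
eigenvalue histograms, and cuts the complete-linkage dendrogram at k=3.
"""

from metacentrality import (
    FixtureSpec,
    cluster_networks,
    laplacian_spectrum,
    make_random_network,
    pairwise_distances,
)

nets = {}
for family in ("bipartite_like", "motif_duplication", "community"):
    for seed in range(3):
        nets[f"{family}:{seed}"] = make_random_network(FixtureSpec(family, 80, seed=seed))

print("largest / median eigenvalue per network:")
for name, net in sorted(nets.items()):
    eig = laplacian_spectrum(net).eigenvalues
    print(f"  {name:22s} max={eig[-1]:.3f} median={eig[len(eig) // 2]:.3f}")

d, names = pairwise_distances(nets)
result = cluster_networks(d, names, k=3)
print("\ncomplete-linkage clusters at k=3 (EMD on spectrum histograms):")
clusters: dict[int, list[str]] = {}
for name, label in result.labels.items():
    clusters.setdefault(label, []).append(name)
for label, members in sorted(clusters.items()):
    print(f"  cluster {label}: {sorted(members)}")
print("\nEach cluster gathers exactly one generative family: spectral shape")
print("alone separates bipartite-like, duplication-grown and community graphs.")
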