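"""Group departments by the semantic similarity of their papers' abstracts.

Three synthetic topics with disjoint vocabularies stand in for research
fields. Word vectors are trained on the abstract corpus, each abstract is
embedded as the L2-normalized mean of its token vectors, departments are
profiled by their mean abstract vector, reduced to 2-D with t-SNE
(perplexity 7) and clustered with k-means. Departments are then ranked by
index value *within* each cluster — cross-cluster comparisons are
discouraged because reporting standards differ between fields.
"""

import numpy as np

from rtindex import semcluster

topics = {
    "neuro": "neuron synapse cortex dendrite plasticity circuit spike".split(),
    "immuno": "lymphocyte cytokine antigen macrophage vaccine pathogen".split(),
    "compbio": "genome transcriptome variant alignment pipeline chromatin".split(),
}
rng = np.random.default_rng(0)
docs, dept_names = [], []
for topic, vocab in topics.items():
    for i in range(12):
        docs.append(" ".join(rng.choice(vocab, 30)))
        dept_names.append(f"Department of {topic.title()} {i}")

model = semcluster.train_embeddings(docs, sample_fraction=1.0, dim=30, seed=0)
print(f"trained {len(model.vocab)}-word embedding model, dim {model.dim}")

profiles = [
    semcluster.DepartmentProfile(
        department=name, institution_id="INST00001", n_papers=250,
        mean_vector=semcluster.embed_abstract(model, doc).vector,
        rti=round(3.0 + rng.random() * 3, 2),
    )
    for name, doc in zip(dept_names, docs)
]
labels, coords = semcluster.cluster_departments(profiles, k=3, perplexity=7, seed=0)
table = semcluster.rank_within_clusters(profiles, labels, coords)
print(table.head(12).to_string(index=False))
# Departments sharing a topic vocabulary land in the same cluster; the
# rank_in_cluster column orders them by index value within their field.
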