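"""End-to-end convenience wrapper: cohort → features → DPG → GNN → clusters.

Composes the library modules with their defaults so the full subphenotyping
pipeline can be run in one call on an in-memory cohort; each stage remains
individually accessible for finer control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import cluster as cl
from . import featurize, gnn
from .dpg import ProgressionGraph, build_dpg
from .synth import GeneratorConfig, SyntheticCohort, generate_cohort


@dataclass
class PipelineResult:
    synthetic: SyntheticCohort | None
    featurized: featurize.FeaturizedCohort
    graph: ProgressionGraph
    train_result: gnn.TrainResult
    embeddings: np.ndarray
    patient_ids: list
    sequences: list
    model: cl.ClusterModel | None = None
    extras: dict = field(default_factory=dict)

    def true_subtypes(self) -> np.ndarray:
        """Planted subtype per clustered patient (synthetic cohorts only)."""
        gt = self.synthetic.ground_truth.set_index("patient_id")["subtype"]
        return gt.loc[self.patient_ids].to_numpy()


def run_pipeline(config: GeneratorConfig, k_neighbors: int = 25,
                 encoder: gnn.EncoderConfig | None = None,
                 n_clusters: int | None = None, cluster_seed: int = 0,
                 n_init: int = 3,
                 representation: str = "patient_subspace") -> PipelineResult:
    """Run the full pipeline on a freshly generated synthetic cohort.

    ``representation`` selects the post-processing of node embeddings
    before sequence building: 'patient_subspace' (whiten + between-patient
    PCA, the default), 'whiten', 'zscore' or 'raw'.
    """
    synthetic = generate_cohort(config)
    feat = featurize.vectorize(synthetic.cohort, synthetic.code_maps)
    graph = build_dpg(feat, k=k_neighbors)
    cfg = encoder or gnn.EncoderConfig(seed=config.seed)
    result = gnn.train(graph, cfg)
    emb = result.embeddings()
    if representation == "patient_subspace":
        emb = cl.patient_subspace(emb, graph.patient_ids())
    elif representation == "whiten":
        emb = cl.whiten_embeddings(emb)
    pids, seqs = cl.embedding_sequences(graph, emb)
    if representation == "zscore":
        seqs = cl.scale_sequences(seqs)
    model = None
    if n_clusters is not None:
        model = cl.ts_kmeans(seqs, n_clusters, seed=cluster_seed,
                             n_init=n_init, patient_ids=pids)
    return PipelineResult(synthetic=synthetic, featurized=feat, graph=graph,
                          train_result=result, embeddings=emb,
                          patient_ids=pids, sequences=seqs, model=model)
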