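"""Independent oracle implementations shared by the metric tests.

These deliberately re-derive the evaluation protocol with naive loops and
set arithmetic so the vectorized evaluator can be checked against them.
"""

import numpy as np

from leafseg.cloud import LEAF, STEM, LabeledCloud
from leafseg.clustering import InstancePrediction
from leafseg.metrics import AP_THRESHOLDS, scene_instances


def make_scene(rng, n_points=200, n_instances=4, noise=0.3):
    """A random scene: ground truth plus a corrupted prediction."""
    sem = np.full(n_points, LEAF, np.int32)
    sem[: n_points // 10] = STEM
    inst = np.full(n_points, -1, np.int32)
    leaf_idx = np.flatnonzero(sem == LEAF)
    chunks = np.array_split(leaf_idx, n_instances)
    for k, c in enumerate(chunks):
        inst[c] = k
    cloud = LabeledCloud(rng.normal(size=(n_points, 3)), None, sem, inst)
    # prediction: per-point corruption of the ground truth
    pred_ids = inst.copy()
    flip = rng.random(n_points) < noise
    pred_ids[flip & (inst >= 0)] = rng.integers(0, n_instances, int((flip & (inst >= 0)).sum()))
    pred_sem = sem.copy()
    sem_flip = rng.random(n_points) < noise / 3
    pred_sem[sem_flip] = rng.integers(0, 3, int(sem_flip.sum()))
    # drop an instance occasionally (only when corruption is requested)
    if noise > 0 and rng.random() < 0.3 and n_instances > 1:
        pred_ids[pred_ids == n_instances - 1] = -1
    k = int(pred_ids.max()) + 1 if (pred_ids >= 0).any() else 0
    sizes = np.array([(pred_ids == i).sum() for i in range(k)], float)
    conf = sizes / max(1, sizes.sum())
    stem_id = None
    if (pred_sem == STEM).any():
        stem_id = k
        pred_ids = pred_ids.copy()
        pred_ids[pred_sem == STEM] = stem_id
        conf = np.append(conf, (pred_sem == STEM).mean())
    pred = InstancePrediction(pred_ids, np.zeros((k, 1)), conf, pred_sem,
                              stem_instance_id=stem_id)
    return pred, cloud


def naive_evaluate(preds, gts):
    out = {}
    for cls in (STEM, LEAF):
        instances, gt_instances = [], []
        for s, (p, c) in enumerate(zip(preds, gts)):
            pi, gi = scene_instances(c, p, scene=s)
            instances += [x for x in pi if x.cls == cls]
            gt_instances += [x for x in gi if x.cls == cls]
        if not gt_instances:
            continue
        aps = {}
        for thr in list(AP_THRESHOLDS) + [0.25]:
            ranked = sorted(range(len(instances)),
                            key=lambda i: (-instances[i].confidence,
                                           -len(instances[i].points), i))
            used = set()
            flags = []
            for i in ranked:
                best, bj = 0.0, None
                for j, g in enumerate(gt_instances):
                    if j in used or g.scene != instances[i].scene:
                        continue
                    inter = len(set(instances[i].points) & set(g.points))
                    union = len(set(instances[i].points) | set(g.points))
                    iou = inter / union if union else 0.0
                    if iou >= thr and iou > best:
                        best, bj = iou, j
                if bj is not None:
                    used.add(bj)
                    flags.append(1)
                else:
                    flags.append(0)
            # literal all-point PR integration with right-to-left envelope
            tp = 0
            pr = []
            for rank, f in enumerate(flags, start=1):
                tp += f
                pr.append((tp / len(gt_instances), tp / rank))
            ap = 0.0
            prev_r = 0.0
            for idx, (r, _) in enumerate(pr):
                if r > prev_r:
                    env = max(p2 for r2, p2 in pr[idx:])
                    ap += (r - prev_r) * env
                    prev_r = r
            aps[round(float(thr), 2)] = ap
        out[cls] = {
            "AP": float(np.mean([aps[round(float(t), 2)] for t in AP_THRESHOLDS])),
            "AP50": aps[0.5],
            "AP25": aps[0.25],
        }
    return out


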