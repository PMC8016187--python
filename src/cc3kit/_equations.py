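"""Frozen spin-adapted working equations of the closed-shell CC3 model.

Each term is ``(coefficient, einsum specification, operand names)``.  Index
letters: a, b (and c, d, e as internals) are virtual; i, j (k, l, m) occupied.
Operands named t2/r2/l2 are (nv, no, nv, no) amplitude blocks, t3/l3/r3 are
(nv, no, nv, no, nv, no) triples tensors, g is the full dressed two-electron
integral set in chemists' notation and F the dressed Fock matrix.  Doubles
outputs marked "pair-symmetrized" are completed as ``x + x.transpose(2,3,0,1)``.

Every coefficient below was determined and verified to machine precision
against an exact determinant-space evaluation of the model.
"""

# ---------------------------------------------------------------------------
# dressed CCSD (CCD-form) residual
# ---------------------------------------------------------------------------

OMEGA1_LIN = [
    (2.0, "aick,kc->ai", ("t2", "F")),
    (-1.0, "akci,kc->ai", ("t2", "F")),
    (-2.0, "akcl,kilc->ai", ("t2", "g")),
    (1.0, "akcl,kcli->ai", ("t2", "g")),
    (2.0, "cidk,ackd->ai", ("t2", "g")),
    (-1.0, "cidk,adkc->ai", ("t2", "g")),
]

# pair-symmetrized
OMEGA2_LIN = [
    (-1.0, "aibk,kj->aibj", ("t2", "F")),
    (1.0, "aicj,bc->aibj", ("t2", "F")),
    (2.0, "aick,bjkc->aibj", ("t2", "g")),
    (-1.0, "aick,bckj->aibj", ("t2", "g")),
    (-1.0, "akci,bjkc->aibj", ("t2", "g")),
    (0.5, "akbl,kilj->aibj", ("t2", "g")),
    (-1.0, "akcj,bcki->aibj", ("t2", "g")),
    (0.5, "cidj,acbd->aibj", ("t2", "g")),
]

# pair-symmetrized
OMEGA2_QUAD = [
    (-2.0, "aibk,cjdl,kcld->aibj", ("t2", "t2", "g")),
    (1.0, "aibk,cjdl,kdlc->aibj", ("t2", "t2", "g")),
    (-1.0, "aicj,bkdl,kcld->aibj", ("t2", "t2", "g")),
    (1.5, "aick,bjdl,kcld->aibj", ("t2", "t2", "g")),
    (-0.5, "aick,bjdl,kdlc->aibj", ("t2", "t2", "g")),
    (-1.0, "aick,bldj,kcld->aibj", ("t2", "t2", "g")),
    (-1.0, "ajci,bkdl,kcld->aibj", ("t2", "t2", "g")),
    (1.0, "ajci,bkdl,kdlc->aibj", ("t2", "t2", "g")),
    (0.5, "akci,bldj,kdlc->aibj", ("t2", "t2", "g")),
    (0.5, "akbl,cidj,kcld->aibj", ("t2", "t2", "g")),
    (0.5, "ajck,bidl,kcld->aibj", ("t2", "t2", "g")),
    (-0.5, "ajck,bidl,kdlc->aibj", ("t2", "t2", "g")),
    (-1.0, "akcj,bidl,kcld->aibj", ("t2", "t2", "g")),
    (1.0, "akcj,bidl,kdlc->aibj", ("t2", "t2", "g")),
    (0.5, "akcj,bldi,kcld->aibj", ("t2", "t2", "g")),
]

# ---------------------------------------------------------------------------
# CC3 triples
# ---------------------------------------------------------------------------

# numerator of the triples amplitudes; tau3 = -P^(W) / eps3 with P^ the sum
# over the six simultaneous permutations of the pairs (ai), (bj), (ck)
W_TERMS = [
    (1.0, "aidj,bdck->aibjck", ("t2", "g")),
    (-1.0, "aibl,cklj->aibjck", ("t2", "g")),
]

COUPLING1 = [
    (2.0, "aickdl,kcld->ai", ("t3", "g")),
    (-1.0, "aickdl,kdlc->ai", ("t3", "g")),
    (-2.0, "akcidl,kcld->ai", ("t3", "g")),
    (1.0, "akcidl,kdlc->ai", ("t3", "g")),
]

# pair-symmetrized
COUPLING2 = [
    (1.0, "aibjck,kc->aibj", ("t3", "F")),
    (-1.0, "aibkcj,kc->aibj", ("t3", "F")),
    (-2.0, "aibkcl,kjlc->aibj", ("t3", "g")),
    (1.0, "aibkcl,kclj->aibj", ("t3", "g")),
    (2.0, "aicjdk,bckd->aibj", ("t3", "g")),
    (-1.0, "aicjdk,bdkc->aibj", ("t3", "g")),
    (1.0, "akblci,kclj->aibj", ("t3", "g")),
    (-1.0, "akcidj,bdkc->aibj", ("t3", "g")),
]

# ---------------------------------------------------------------------------
# densities (dressed frame, before the T1 back-transformation)
# ---------------------------------------------------------------------------

# ground-state / right transition density D^{m0}: bra (l1, l2, l3), no R.
# The reference part is 2*delta on the occupied diagonal; D_vo = l1 exactly.
DENSITY_GS = {
    "oo": [
        (-2.0, "cjdk,cidk->ij", ("l2", "t2")),
        (-3.0, "cjdkel,cidkel->ij", ("l3", "t3")),
    ],
    "vv": [
        (2.0, "akcl,bkcl->ab", ("l2", "t2")),
        (3.0, "akcldm,bkcldm->ab", ("l3", "t3")),
    ],
    "ov": [
        (2.0, "ck,aick->ia", ("l1", "t2")),
        (-1.0, "ck,akci->ia", ("l1", "t2")),
        (2.0, "ckdl,aickdl->ia", ("l2", "t3")),
        (-2.0, "ckdl,akcidl->ia", ("l2", "t3")),
        (-6.0, "ckdlem,akdl,ciem->ia", ("l3", "t2", "t2")),
    ],
    "vo": [
        (1.0, "ai->ai", ("l1",)),
    ],
}

#: the single ov-block term by which the EOM-form ground-state density
#: differs from the exact energy derivative (response form)
DENSITY_EOM_ONLY_OV = [(-6.0, "ckdlem,akdl,ciem->ia", ("l3", "t2", "t2"))]

# left transition density D~^{0m}: bra (1 + Lambda), ket R; the reference
# bra part is 2 r1^T in the ov block, and r_m times the ground-state density
# is added separately.  "tr" marks delta * trace terms on oo/vv diagonals.
DENSITY_TDM = {
    "oo": [
        (-1.0, "cj,ci->ij", ("l1", "r1")),
        (2.0, "ck,ck->", ("l1", "r1")),
        (-2.0, "cjdk,cidk->ij", ("l2", "r2")),
        (2.0, "ckdl,ckdl->", ("l2", "r2")),
        (-3.0, "cjdkel,cidkel->ij", ("l3", "r3")),
        (2.0, "ckdlem,ckdlem->", ("l3", "r3")),
        (-6.0, "cjdkel,dk,ciel->ij", ("l3", "r1", "t2")),
    ],
    "vv": [
        (1.0, "ak,bk->ab", ("l1", "r1")),
        (2.0, "akcl,bkcl->ab", ("l2", "r2")),
        (3.0, "akcldm,bkcldm->ab", ("l3", "r3")),
        (6.0, "akcldm,cl,bkdm->ab", ("l3", "r1", "t2")),
    ],
    "ov": [
        (2.0, "ia->ia", ("r1t",)),  # reference part, r1 transposed
        (2.0, "ck,aick->ia", ("l1", "r2")),
        (-1.0, "ck,akci->ia", ("l1", "r2")),
        (2.0, "ckdl,aickdl->ia", ("l2", "r3")),
        (-2.0, "ckdl,akcidl->ia", ("l2", "r3")),
        (-2.0, "ckdl,ci,akdl->ia", ("l2", "r1", "t2")),
        (-2.0, "ckdl,ak,cidl->ia", ("l2", "r1", "t2")),
        (4.0, "ckdl,ck,aidl->ia", ("l2", "r1", "t2")),
        (-2.0, "ckdl,ck,aldi->ia", ("l2", "r1", "t2")),
        (-6.0, "ckdlem,cidl,akem->ia", ("l3", "r2", "t2")),
        (-6.0, "ckdlem,akdl,ciem->ia", ("l3", "r2", "t2")),
        (6.0, "ckdlem,ckdl,aiem->ia", ("l3", "r2", "t2")),
        (-3.0, "ckdlem,ckdl,amei->ia", ("l3", "r2", "t2")),
        (-3.0, "ckdlem,ci,akdlem->ia", ("l3", "r1", "t3")),
        (-3.0, "ckdlem,ak,cidlem->ia", ("l3", "r1", "t3")),
        (6.0, "ckdlem,ck,aidlem->ia", ("l3", "r1", "t3")),
        (-6.0, "ckdlem,ck,aldiem->ia", ("l3", "r1", "t3")),
    ],
    "vo": [
        (2.0, "aick,ck->ai", ("l2", "r1")),
        (3.0, "aickdl,ckdl->ai", ("l3", "r2")),
    ],
}
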