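# Model-variant ledger: each variant is a constraint set applied to the full
# 19-parameter kinetic model (V0).  Constraint kinds:
#   fix:   pin named parameter slots to a constant (removed from free vector)
#   share: collapse a group of slots to a single free value
#   drop:  replace a functional term by its stated limit
#          growth_monod      C/(K_G+C) -> C          (large K_G, rescaled psi_max)
#          growth_resource   C/(K_G+C) -> 1          (no resource dependence)
#          lag               t^n/(K_L^n+t^n) -> 1    (no lag phase)
#          transfer_monod    C/(K_T+C) -> C          (large K_T, rescaled gamma_max)
#          transfer_resource C/(K_T+C) -> 1          (constant transfer rate)
#          depletion         population's resource-depletion term absent
# A nested list element (YAML alias of another variant's constraint list) is
# flattened by the loader.  Where the published narrative admits more than one
# constraint set with the right kinetic-parameter count (the V10/V11/V12 pair
# assignment), the choice made here is editable.
variants:
  - name: V0
    description: Full model; 19 free kinetic parameters.
    constraints: []

  - name: V1
    description: Hill coefficients fixed at 1.
    constraints:
      - fix: {params: [n_D, n_R, n_T], value: 1.0}

  - name: V2
    description: V1 with growth and transfer Monod terms in their linear-in-C limits.
    constraints: &v2base
      - fix: {params: [n_D, n_R, n_T], value: 1.0}
      - drop: {term: growth_monod, pops: [D, R, T]}
      - drop: {term: transfer_monod, pops: [D, T]}

  - name: V3
    description: V2 with equal recipient and transconjugant depletion rates.
    constraints:
      - *v2base
      - share: {params: [e_R, e_T], as: e_RT}

  - name: V4
    description: V2 with one shared depletion rate.
    constraints:
      - *v2base
      - share: {params: [e_D, e_R, e_T], as: e}

  - name: V5
    description: V2 with one shared lag half-time.
    constraints:
      - *v2base
      - share: {params: [K_L_D, K_L_R, K_L_T], as: K_L}

  - name: V6
    description: V5 with equal recipient and transconjugant depletion rates.
    constraints:
      - *v2base
      - share: {params: [K_L_D, K_L_R, K_L_T], as: K_L}
      - share: {params: [e_R, e_T], as: e_RT}

  - name: V7
    description: V6 with one shared transfer rate (no transitory derepression).
    constraints: &v7base
      - *v2base
      - share: {params: [K_L_D, K_L_R, K_L_T], as: K_L}
      - share: {params: [e_R, e_T], as: e_RT}
      - share: {params: [gamma_max_D, gamma_max_T], as: gamma_max}

  - name: V8
    description: V7 with one shared depletion rate.
    constraints:
      - *v2base
      - share: {params: [K_L_D, K_L_R, K_L_T], as: K_L}
      - share: {params: [e_D, e_R, e_T], as: e}
      - share: {params: [gamma_max_D, gamma_max_T], as: gamma_max}

  - name: V9
    description: V7 with the lag phase removed.
    constraints:
      - *v2base
      - drop: {term: lag, pops: [D, R, T]}
      - share: {params: [e_R, e_T], as: e_RT}
      - share: {params: [gamma_max_D, gamma_max_T], as: gamma_max}

  - name: V10
    description: V7 with equal donor and recipient growth rates.
    constraints:
      - *v7base
      - share: {params: [psi_max_D, psi_max_R], as: psi_max_DR}

  - name: V11
    description: V7 with equal donor and transconjugant growth rates.
    constraints:
      - *v7base
      - share: {params: [psi_max_D, psi_max_T], as: psi_max_DT}

  - name: V12
    description: V7 with equal recipient and transconjugant growth rates.
    constraints:
      - *v7base
      - share: {params: [psi_max_R, psi_max_T], as: psi_max_RT}

  - name: V13
    description: >
      Simonsen-style model: shared growth rate with one Monod constant, no
      lag, one shared depletion rate, one constant transfer rate.
    constraints:
      - drop: {term: lag, pops: [D, R, T]}
      - drop: {term: transfer_resource, pops: [D, T]}
      - share: {params: [psi_max_D, psi_max_R, psi_max_T], as: psi_max}
      - share: {params: [K_G_D, K_G_R, K_G_T], as: K_G}
      - share: {params: [e_D, e_R, e_T], as: e}
      - share: {params: [gamma_max_D, gamma_max_T], as: gamma_max}

  - name: V14
    description: >
      Levin-style model: one constant growth rate, one constant mass-action
      transfer rate, no lag and no resource.
    constraints:
      - drop: {term: lag, pops: [D, R, T]}
      - drop: {term: growth_resource, pops: [D, R, T]}
      - drop: {term: transfer_resource, pops: [D, T]}
      - fix: {params: [e_D, e_R, e_T], value: 0.0}
      - share: {params: [psi_max_D, psi_max_R, psi_max_T], as: psi_max}
      - share: {params: [gamma_max_D, gamma_max_T], as: gamma_max}

  - name: V15
    description: >
      Selected model: V7 with transconjugant growth fixed at zero and the
      transconjugant depletion term absent.
    free_order: [psi_max_R, psi_max_D, K_L, gamma_max, e_R, e_D]
    constraints:
      - *v2base
      - fix: {params: [psi_max_T], value: 0.0}
      - drop: {term: depletion, pops: [T]}
      - share: {params: [K_L_D, K_L_R, K_L_T], as: K_L}
      - share: {params: [gamma_max_D, gamma_max_T], as: gamma_max}
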