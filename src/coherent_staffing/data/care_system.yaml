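# Reference care system: a 70-bed two-department perinatology service.
# Units: N1 neonatal intensive care, N2 neonatal post-intensive care,
# N3 neonatal high/medium care, O1 maternity ward (7 newborn beds O1n,
# 25 adult beds O1a), O2 obstetric high care, O3 delivery rooms.
name: perinatology-70-beds
units:
  - {id: N1, department: Neonatology, beds: 14, patient_group: newborn, specialization_rank: 1}
  - {id: N2, department: Neonatology, beds: 4, patient_group: newborn, specialization_rank: 2}
  - {id: N3, department: Neonatology, beds: 11, patient_group: newborn, specialization_rank: 3}
  - {id: O1n, department: Obstetrics, beds: 7, patient_group: newborn, specialization_rank: 3}
  - {id: O1a, department: Obstetrics, beds: 25, patient_group: adult, specialization_rank: 3}
  - {id: O2, department: Obstetrics, beds: 3, patient_group: adult, specialization_rank: 2}
  - {id: O3, department: Obstetrics, beds: 6, patient_group: adult, specialization_rank: 1}
# Nurses scheduled per shift type.  The single O1 column is split across
# O1n/O1a proportionally to beds when the configuration is loaded.
roster:
  day: {N1: 12, N2: 2, N3: 4, O1: 6, O2: 1, O3: 3}
  evening: {N1: 8, N2: 2, N3: 2, O1: 5, O2: 1, O3: 3}
  night: {N1: 7, N2: 2, N3: 2, O1: 2, O2: 1, O3: 3}
# Patients one nurse covers, per shift type and unit.
ntp_ratio:
  day: {N1: 1, N2: 2, N3: 3, O1: 5, O2: 3, O3: 2}
  evening: {N1: 2, N2: 2, N3: 6, O1: 6, O2: 3, O3: 2}
  night: {N1: 2, N2: 2, N3: 6, O1: 16, O2: 3, O3: 2}
# Registered nurses by qualification group.  Groups spanning several
# units are kept as qualification groups, not split per unit.
registry:
  N1: 59
  N2: 40
  N3: 14
  O1+O2+O3: 53
  O1+O2: 5
  O1: 5
training:
  cost_per_nurse_eur: 20000
  # Obstetrics nurses needing cross-training to pool the department
  # (two-department layout); a case-study interview figure.
  config1_obstetrics_trainees: 10
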