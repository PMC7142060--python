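# Default list of DICOM attribute keywords treated as protected health
# information (PHI). One keyword per line; lines starting with '#' are
# comments. Private tags (odd group number) are always treated as PHI in
# addition to this list.
PatientName
PatientID
OtherPatientIDs
PatientBirthDate
PatientBirthTime
PatientAddress
PatientTelephoneNumbers
ReferringPhysicianName
PerformingPhysicianName
PhysiciansOfRecord
OperatorsName
InstitutionName
InstitutionAddress
InstitutionalDepartmentName
AccessionNumber
StationName
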