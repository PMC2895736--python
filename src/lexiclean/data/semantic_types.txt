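# Semantic Network type names (mid-2000s snapshot), one per line.
# Used by the semantic-type rewrite rule to recognise "(Type Name)" suffixes.
Organism
Plant
Alga
Fungus
Virus
Rickettsia or Chlamydia
Bacterium
Animal
Invertebrate
Vertebrate
Amphibian
Bird
Fish
Reptile
Mammal
Human
Anatomical Structure
Embryonic Structure
Congenital Abnormality
Acquired Abnormality
Fully Formed Anatomical Structure
Body System
Body Part, Organ, or Organ Component
Tissue
Cell
Cell Component
Gene or Genome
Body Location or Region
Body Space or Junction
Body Substance
Organism Attribute
Finding
Laboratory or Test Result
Injury or Poisoning
Biologic Function
Physiologic Function
Organism Function
Mental Process
Organ or Tissue Function
Cell Function
Molecular Function
Genetic Function
Pathologic Function
Disease or Syndrome
Mental or Behavioral Dysfunction
Cell or Molecular Dysfunction
Experimental Model of Disease
Event
Activity
Behavior
Social Behavior
Individual Behavior
Daily or Recreational Activity
Occupational Activity
Health Care Activity
Laboratory Procedure
Diagnostic Procedure
Therapeutic or Preventive Procedure
Research Activity
Molecular Biology Research Technique
Governmental or Regulatory Activity
Educational Activity
Machine Activity
Phenomenon or Process
Human-caused Phenomenon or Process
Environmental Effect of Humans
Natural Phenomenon or Process
Entity
Physical Object
Manufactured Object
Medical Device
Research Device
Conceptual Entity
Idea or Concept
Temporal Concept
Qualitative Concept
Quantitative Concept
Spatial Concept
Geographic Area
Molecular Sequence
Nucleotide Sequence
Amino Acid Sequence
Carbohydrate Sequence
Regulation or Law
Occupation or Discipline
Biomedical Occupation or Discipline
Organization
Health Care Related Organization
Professional Society
Self-help or Relief Organization
Group
Professional or Occupational Group
Population Group
Family Group
Age Group
Patient or Disabled Group
Group Attribute
Chemical
Chemical Viewed Structurally
Organic Chemical
Steroid
Eicosanoid
Nucleic Acid, Nucleoside, or Nucleotide
Organophosphorus Compound
Amino Acid, Peptide, or Protein
Carbohydrate
Lipid
Chemical Viewed Functionally
Pharmacologic Substance
Biomedical or Dental Material
Biologically Active Substance
Neuroreactive Substance or Biogenic Amine
Hormone
Enzyme
Vitamin
Immunologic Factor
Indicator, Reagent, or Diagnostic Aid
Hazardous or Poisonous Substance
Substance
Food
Functional Concept
Intellectual Product
Language
Sign or Symptom
Classification
Anatomical Abnormality
Neoplastic Process
Receptor
Archaeon
Antibiotic
Element, Ion, or Isotope
Inorganic Chemical
Clinical Drug
Clinical Attribute
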