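# Synthetic surname table for testing the surname-based ethnicity assignment.
# This is NOT the 1990 U.S. Census Spanish Surname List; tier labels are
# invented for test coverage of all five categories.
# Format: SURNAME<TAB>CATEGORY
GARCIA	HEAVILY
RODRIGUEZ	HEAVILY
MARTINEZ	HEAVILY
HERNANDEZ	HEAVILY
LOPEZ	HEAVILY
GONZALEZ	HEAVILY
PEREZ	HEAVILY
SANCHEZ	HEAVILY
RAMIREZ	HEAVILY
TORRES	HEAVILY
FLORES	HEAVILY
RIVERA	HEAVILY
GOMEZ	HEAVILY
DIAZ	HEAVILY
DE LA CRUZ	HEAVILY
FERNANDEZ	GENERALLY
MORENO	GENERALLY
ORTIZ	GENERALLY
CASTILLO	GENERALLY
ROMERO	GENERALLY
ALVAREZ	GENERALLY
MENDOZA	GENERALLY
RUIZ	GENERALLY
SILVA	MODERATELY
MEDINA	MODERATELY
AGUILAR	MODERATELY
VEGA	MODERATELY
SERRANO	MODERATELY
MARINO	MODERATELY
COSTA	MODERATELY
PINTO	OCCASIONALLY
FONTANA	OCCASIONALLY
BELLO	OCCASIONALLY
FERRARI	OCCASIONALLY
LUNA-REYES	OCCASIONALLY
SALAS	OCCASIONALLY
SMITH	RARELY
JOHNSON	RARELY
WILLIAMS	RARELY
BROWN	RARELY
JONES	RARELY
MILLER	RARELY
DAVIS	RARELY
WILSON	RARELY
ANDERSON	RARELY
TAYLOR	RARELY
THOMAS	RARELY
MOORE	RARELY
CLARK	RARELY
LEWIS	RARELY
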