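<?xml version="1.0" encoding="utf-8"?>
<aiml version="subset-1.0">
  <topic name="leave_conversation" description="frases de despedida para el paciente">
    <category role="trigger">
      <pattern>ADIÓS</pattern>
      <template><random>
        <li>Me dio mucho gusto platicar contigo<condition name="patient_name">, <get name="patient_name"/></condition>. ¡Hasta pronto!</li>
        <li>Gracias por esta plática tan bonita. Descansa mucho. ¡Adiós!</li>
        <li>Aquí estaré cuando quieras platicar otra vez. ¡Hasta luego!</li>
      </random></template>
    </category>
    <category role="trigger">
      <pattern>_ ADIÓS</pattern>
      <template><srai>ADIÓS</srai></template>
    </category>
    <category role="trigger">
      <pattern>ADIÓS _</pattern>
      <template><srai>ADIÓS</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ ADIÓS _</pattern>
      <template><srai>ADIÓS</srai></template>
    </category>
    <category role="trigger">
      <pattern>HASTA LUEGO</pattern>
      <template><srai>ADIÓS</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ HASTA LUEGO</pattern>
      <template><srai>ADIÓS</srai></template>
    </category>
    <category role="trigger">
      <pattern>HASTA LUEGO _</pattern>
      <template><srai>ADIÓS</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ HASTA LUEGO _</pattern>
      <template><srai>ADIÓS</srai></template>
    </category>
    <category role="trigger">
      <pattern>YA ME VOY</pattern>
      <template><srai>ADIÓS</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ YA ME VOY</pattern>
      <template><srai>ADIÓS</srai></template>
    </category>
    <category role="trigger">
      <pattern>YA ME VOY _</pattern>
      <template><srai>ADIÓS</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ YA ME VOY _</pattern>
      <template><srai>ADIÓS</srai></template>
    </category>
    <category role="trigger">
      <pattern>ME QUIERO IR</pattern>
      <template><srai>ADIÓS</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ ME QUIERO IR</pattern>
      <template><srai>ADIÓS</srai></template>
    </category>
    <category role="trigger">
      <pattern>ME QUIERO IR _</pattern>
      <template><srai>ADIÓS</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ ME QUIERO IR _</pattern>
      <template><srai>ADIÓS</srai></template>
    </category>
    <category role="trigger">
      <pattern>YA ME CANSÉ</pattern>
      <template><srai>ADIÓS</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ YA ME CANSÉ</pattern>
      <template><srai>ADIÓS</srai></template>
    </category>
    <category role="trigger">
      <pattern>YA ME CANSÉ _</pattern>
      <template><srai>ADIÓS</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ YA ME CANSÉ _</pattern>
      <template><srai>ADIÓS</srai></template>
    </category>
  </topic>
</aiml>
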