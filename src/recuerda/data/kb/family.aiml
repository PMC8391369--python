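<?xml version="1.0" encoding="utf-8"?>
<aiml version="subset-1.0">
  <topic name="family" description="familiares importantes para el paciente">
    <category role="trigger">
      <pattern>FAMILIA</pattern>
      <template><random>
        <li>¿Es verdad que <get name="fam1_name"/> es tu <get name="parentesco_fam1"/>?</li>
        <li>¿Te gustaría platicar de tu <get name="parentesco_fam1"/> <get name="fam1_name"/>?</li>
        <li>La familia es un gran tesoro. ¿Quién de tu familia te hace sonreír más?</li>
      </random></template>
    </category>
    <category role="trigger">
      <pattern>_ FAMILIA</pattern>
      <template><srai>FAMILIA</srai></template>
    </category>
    <category role="trigger">
      <pattern>FAMILIA _</pattern>
      <template><srai>FAMILIA</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ FAMILIA _</pattern>
      <template><srai>FAMILIA</srai></template>
    </category>
    <category role="trigger">
      <pattern>HIJOS</pattern>
      <template><srai>FAMILIA</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ HIJOS</pattern>
      <template><srai>FAMILIA</srai></template>
    </category>
    <category role="trigger">
      <pattern>HIJOS _</pattern>
      <template><srai>FAMILIA</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ HIJOS _</pattern>
      <template><srai>FAMILIA</srai></template>
    </category>
    <category role="trigger">
      <pattern>ESPOSO</pattern>
      <template><srai>FAMILIA</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ ESPOSO</pattern>
      <template><srai>FAMILIA</srai></template>
    </category>
    <category role="trigger">
      <pattern>ESPOSO _</pattern>
      <template><srai>FAMILIA</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ ESPOSO _</pattern>
      <template><srai>FAMILIA</srai></template>
    </category>
    <category role="trigger">
      <pattern>ESPOSA</pattern>
      <template><srai>FAMILIA</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ ESPOSA</pattern>
      <template><srai>FAMILIA</srai></template>
    </category>
    <category role="trigger">
      <pattern>ESPOSA _</pattern>
      <template><srai>FAMILIA</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ ESPOSA _</pattern>
      <template><srai>FAMILIA</srai></template>
    </category>
    <category role="trigger">
      <pattern>HERMANOS</pattern>
      <template><srai>FAMILIA</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ HERMANOS</pattern>
      <template><srai>FAMILIA</srai></template>
    </category>
    <category role="trigger">
      <pattern>HERMANOS _</pattern>
      <template><srai>FAMILIA</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ HERMANOS _</pattern>
      <template><srai>FAMILIA</srai></template>
    </category>
    <category>
      <pattern>SÍ</pattern>
      <template><random>
        <li>¡Qué bonito! ¿Qué recuerdos felices tienes con <get name="fam1_name"/>?</li>
        <li>Cuéntame, ¿qué es lo que más te gusta de <get name="fam1_name"/>?</li>
      </random></template>
    </category>
    <category>
      <pattern>SI</pattern>
      <template><srai>SÍ</srai></template>
    </category>
    <category>
      <pattern>SÍ _</pattern>
      <template><srai>SÍ</srai></template>
    </category>
    <category>
      <pattern>SI _</pattern>
      <template><srai>SÍ</srai></template>
    </category>
    <category>
      <pattern>NO</pattern>
      <template>Entiendo. ¿De qué persona querida te gustaría platicar?</template>
    </category>
    <category role="fallback">
      <pattern>*</pattern>
      <template><random>
        <li>La familia siempre da mucho de qué hablar. ¿Me cuentas más de tu familia?</li>
        <li>Qué bonito. ¿Qué solían hacer juntos en familia?</li>
      </random></template>
    </category>
  </topic>
</aiml>
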